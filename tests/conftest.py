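import numpy as np
import pandas as pd
import pytest

from p53eff import ExpressionMatrix, GenePanel, SimulationConfig
from p53eff.simulate import target_names


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, 2 nontumor / 2 tumor."""
    values = pd.DataFrame(
        [[5.0, 6.0, 7.0, 8.0], [1.0, 2.0, 3.0, 4.0], [2.5, 2.5, 2.5, 2.5]],
        index=["TP53", "CDKN1A", "ZNF224"],
        columns=["s1", "s2", "s3", "s4"],
    )
    group = pd.Series(
        ["nontumor", "nontumor", "tumor", "tumor"], index=values.columns, dtype=object
    )
    return ExpressionMatrix(values, group)


@pytest.fixture
def sim_panel():
    """Panel matching the synthetic generator's target names."""
    return GenePanel(regulator="TP53", targets=tuple(target_names(59)))


@pytest.fixture
def default_config():
    return SimulationConfig()


def write_series_matrix_fixture(path, titles, probes, values, samples=None):
    """Minimal GEO-style series-matrix text file (synthetic fixture)."""
    samples = samples or [f"GSM{i + 1}" for i in range(len(titles))]
    lines = [
        '!Series_title\t"synthetic fixture"',
        "!Sample_title\t" + "\t".join(f'"{t}"' for t in titles),
        "!Sample_geo_accession\t" + "\t".join(f'"{s}"' for s in samples),
        "!series_matrix_table_begin",
        '"ID_REF"\t' + "\t".join(f'"{s}"' for s in samples),
    ]
    for probe, row in zip(probes, values):
        lines.append(f'"{probe}"\t' + "\t".join(str(v) for v in row))
    lines.append("!series_matrix_table_end")
    path.write_text("\n".join(lines) + "\n")
    return path
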