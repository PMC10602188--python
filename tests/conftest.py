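import pandas as pd
import pytest

from stabvar import synth


@pytest.fixture(scope="session")
def default_config() -> synth.GeneratorConfig:
    return synth.GeneratorConfig(seed=123)


@pytest.fixture(scope="session")
def annotated_4k(default_config) -> pd.DataFrame:
    """4000 benign + 4000 pathogenic variants at the default conditions."""
    return synth.generate_annotated(default_config, 4000, 4000)


def toy_curation_table() -> pd.DataFrame:
    """Hand-checkable 10-row raw table spanning every curation rule.

    Gene A: 3 benign (af 0.02), 2 pathogenic (af 0.001), 1 conflicting;
    gene B: 1 likely_pathogenic (af 0.001), 3 VUS.  After the conflict drop
    gene A is 100% definitive (dataset 1, 5 rows); gene B has definitive
    fraction 0 but extended fraction 0.25 (dataset 2 only, 1 labelled row).
    """
    rows = []
    for i in range(3):
        rows.append(("GENEA", "PA", 10 + i, "A", "V", "benign", 0.02))
    for i in range(2):
        rows.append(("GENEA", "PA", 20 + i, "R", "H", "pathogenic", 0.001))
    rows.append(("GENEA", "PA", 30, "G", "D", "conflicting", 0.005))
    rows.append(("GENEB", "PB", 5, "W", "C", "likely_pathogenic", 0.001))
    for i in range(3):
        rows.append(("GENEB", "PB", 40 + i, "L", "P", "vus", 0.003))
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "protein_id",
            "position",
            "wt_aa",
            "mut_aa",
            "clin_sig",
            "allele_freq",
        ],
    )


@pytest.fixture
def toy_raw_table() -> pd.DataFrame:
    return toy_curation_table()
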