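import numpy as np
import pandas as pd
import pytest

from synaptoshift import SimulationConfig, load_reference_ratio_table, simulate_study


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_ratio_table()


@pytest.fixture(scope="session")
def small_study():
    """A small paired study with strongly planted shift genes."""
    cfg = SimulationConfig(
        n_genes=300,
        n_subjects_per_group=6,
        frac_de_total=0.05,
        frac_de_synaptic=0.05,
        frac_shift=0.05,
        shift_effect_log2=2.0,
        noise_log2_sd=0.4,
        seed=11,
    )
    return simulate_study(cfg)


def make_sample_sheet(n_control=3, n_case=3, fractions=("total", "synaptic"), **covariates):
    """Minimal hand-built sample sheet for unit tests."""
    rows = []
    for group, prefix, n in (("control", "C", n_control), ("MDD", "M", n_case)):
        for i in range(1, n + 1):
            subject = f"{prefix}{i}"
            for fraction in fractions:
                rows.append(
                    dict(
                        sample_id=f"{subject}_{fraction[:3]}",
                        subject_id=subject,
                        group=group,
                        fraction=fraction,
                    )
                )
    sheet = pd.DataFrame(rows)
    for name, values in covariates.items():
        per_subject = dict(zip(sheet["subject_id"].unique(), values))
        sheet[name] = sheet["subject_id"].map(per_subject)
    return sheet


def make_matrix(values: dict, samples: list[str]) -> pd.DataFrame:
    """Expression matrix from {gene: [per-sample FPKM]}."""
    return pd.DataFrame.from_dict(values, orient="index", columns=samples).rename_axis("gene_id")


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
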