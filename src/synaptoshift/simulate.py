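"""Synthetic paired-fraction expression studies with planted effects.

The generator emulates a two-group (control vs. MDD) postmortem-brain
design in which every subject contributes two RNA-seq profiles: one from
whole-tissue homogenate ("total" fraction) and one from purified
synaptosomes ("synaptic" fraction). FPKM values are log-normal with
additive effects on the log2 scale:

    log2 FPKM(g, s, f, r) = b_g + e_g*[f = synaptic]
                            + d_g^(f)*[r = MDD]
                            + h_g*[r = MDD][f = synaptic]
                            + eps(g, s, f)

where ``b_g`` is the gene's baseline abundance, ``e_g`` its synaptic
enrichment (drawn with a negative mean so most synaptic/total ratios fall
below 1, as observed in brain), ``d_g^(f)`` a planted group effect acting
in the gene's designated fraction, ``h_g`` a planted group-by-fraction
interaction (the "ratio shift"), and ``eps`` i.i.d. subject-level noise.
Values are optionally zeroed at random to exercise downstream
pseudocount/exclusion handling. Everything is reproducible from a single
seed.

Planted genes are the first ``floor(frac * n_genes)`` entries of a seeded
shuffle; by default the DE-in-total, DE-in-synaptic and shift sets are
disjoint slices of one shuffle (set ``allow_overlap=True`` to draw each
set from its own shuffle instead).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .errors import ConfigurationError

log = logging.getLogger(__name__)

_PROPORTION_FIELDS = ("frac_de_total", "frac_de_synaptic", "frac_shift", "dropout_prob")


@dataclass
class SimulationConfig:
    """Parameters of the paired-fraction study generator.

    Defaults describe the study design being emulated: 15 subjects per
    group with two profiles each, a few thousand well-expressed genes,
    synaptic/total ratios with median below 1 (``ratio_log2_mean =
    log2(0.89)``), and planted effects above the 1.3-fold detection
    threshold. ``noise_log2_sd`` is a free choice (no variance estimates
    accompany the published FPKM data); 0.5 on the log2 scale gives
    realistic bulk-RNA-seq subject-to-subject spread.
    """

    n_genes: int = 2000
    n_subjects_per_group: int = 15
    baseline_log2_fpkm_mean: float = 4.0
    baseline_log2_fpkm_sd: float = 1.5
    ratio_log2_mean: float = -0.16812275880832984  # log2(0.89)
    ratio_log2_sd: float = 0.5
    frac_de_total: float = 0.03
    frac_de_synaptic: float = 0.03
    frac_shift: float = 0.02
    de_effect_log2: float = 0.585  # ~1.5-fold, above the 1.3-fold call threshold
    shift_effect_log2: float = 1.0
    noise_log2_sd: float = 0.5
    dropout_prob: float = 0.0
    allow_overlap: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_subjects_per_group < 2:
            raise ConfigurationError("n_subjects_per_group must be >= 2")
        for name in _PROPORTION_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("baseline_log2_fpkm_sd", "ratio_log2_sd", "noise_log2_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not self.allow_overlap and (
            self.frac_de_total + self.frac_de_synaptic + self.frac_shift > 1.0
        ):
            raise ConfigurationError(
                "frac_de_total + frac_de_synaptic + frac_shift exceeds 1 "
                "with disjoint planting (set allow_overlap=True to permit overlap)"
            )


@dataclass
class SimulatedStudy:
    """A generated study: expression, sample sheet, and ground-truth labels."""

    expression: pd.DataFrame  # genes x (4 * n_subjects_per_group) FPKM
    samples: pd.DataFrame
    truth_de_total: frozenset[str]
    truth_de_synaptic: frozenset[str]
    truth_shift: frozenset[str]
    config: SimulationConfig


def _planted_sets(cfg: SimulationConfig, gene_ids: np.ndarray, rng) -> tuple:
    n = cfg.n_genes
    sizes = [int(np.floor(f * n)) for f in (cfg.frac_de_total, cfg.frac_de_synaptic, cfg.frac_shift)]
    if cfg.allow_overlap:
        picks = [rng.permutation(n)[:k] for k in sizes]
    else:
        order = rng.permutation(n)
        offsets = np.cumsum([0] + sizes)
        picks = [order[offsets[i] : offsets[i + 1]] for i in range(3)]
    return tuple(frozenset(gene_ids[p]) for p in picks), picks


def _sample_sheet(cfg: SimulationConfig, rng) -> pd.DataFrame:
    rows = []
    n = cfg.n_subjects_per_group
    for group, prefix in (("control", "C"), ("MDD", "M")):
        for i in range(1, n + 1):
            subject = f"{prefix}{i:03d}"
            # near-balanced sex; antidepressant exposure only in the MDD group
            sex = "male" if (i + (group == "MDD")) % 2 else "female"
            antidep = "yes" if group == "MDD" and rng.random() < 0.4 else "no"
            alcohol = "yes" if rng.random() < 0.2 else "no"
            age = float(np.round(np.clip(rng.normal(50.0, 10.0), 20.0, 85.0), 1))
            pmi = float(np.round(np.clip(rng.normal(20.0, 6.0), 2.0, 40.0), 1))
            ph = float(np.round(np.clip(rng.normal(6.5, 0.25), 5.8, 7.2), 2))
            for fraction, suffix in (("total", "tot"), ("synaptic", "syn")):
                rows.append(
                    dict(
                        sample_id=f"{subject}_{suffix}",
                        subject_id=subject,
                        group=group,
                        fraction=fraction,
                        age=age,
                        pmi=pmi,
                        ph=ph,
                        sex=sex,
                        antidepressant=antidep,
                        alcohol=alcohol,
                    )
                )
    return pd.DataFrame(rows)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a paired two-fraction, two-group FPKM study.

    Deterministic given ``config.seed``: the same configuration yields
    bit-identical matrices, sample sheets and truth sets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_genes)))
    gene_ids = np.array([f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)])

    (truth_de_total, truth_de_synaptic, truth_shift), picks = _planted_sets(
        config, gene_ids, rng
    )
    samples = _sample_sheet(config, rng)

    b = rng.normal(config.baseline_log2_fpkm_mean, config.baseline_log2_fpkm_sd, config.n_genes)
    e = rng.normal(config.ratio_log2_mean, config.ratio_log2_sd, config.n_genes)
    d_total = np.zeros(config.n_genes)
    d_total[picks[0]] = config.de_effect_log2
    d_syn = np.zeros(config.n_genes)
    d_syn[picks[1]] = config.de_effect_log2
    h = np.zeros(config.n_genes)
    h[picks[2]] = config.shift_effect_log2

    is_syn = (samples["fraction"] == "synaptic").to_numpy()
    is_case = (samples["group"] == "MDD").to_numpy()
    log2x = (
        b[:, None]
        + np.outer(e, is_syn)
        + np.outer(d_total, is_case & ~is_syn)
        + np.outer(d_syn, is_case & is_syn)
        + np.outer(h, is_case & is_syn)
        + rng.normal(0.0, config.noise_log2_sd, (config.n_genes, len(samples)))
    )
    fpkm = np.exp2(log2x)
    if config.dropout_prob > 0:
        fpkm[rng.random(fpkm.shape) < config.dropout_prob] = 0.0

    expression = pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"),
                              columns=samples["sample_id"].to_numpy())
    return SimulatedStudy(
        expression=expression,
        samples=samples,
        truth_de_total=truth_de_total,
        truth_de_synaptic=truth_de_synaptic,
        truth_shift=truth_shift,
        config=config,
    )


def truth_frame(study: SimulatedStudy) -> pd.DataFrame:
    """Ground-truth labels as a 0/1 table, one row per gene."""
    genes = study.expression.index
    return pd.DataFrame(
        {
            "gene_id": genes,
            "is_de_total": [int(g in study.truth_de_total) for g in genes],
            "is_de_synaptic": [int(g in study.truth_de_synaptic) for g in genes],
            "is_shift": [int(g in study.truth_shift) for g in genes],
        }
    )


def write_fixtures(study: SimulatedStudy, directory) -> dict[str, Path]:
    """Write expression/sample-sheet/truth TSVs that round-trip through ``io``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "samples": directory / "samples.tsv",
        "truth": directory / "truth.tsv",
    }
    io.write_expression(study.expression, paths["expression"])
    io.write_sample_sheet(study.samples, paths["samples"])
    truth_frame(study).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("is_de_total", "is_de_synaptic", "is_shift"):
        truth[col] = truth[col].astype(int)
    return truth
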