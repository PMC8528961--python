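"""Synthetic lung-allograft methylation cohorts with known ground truth.

The generator produces cohorts carrying the statistical structure the
analysis stages assume, so every stage can be verified by parameter
recovery:

* a true per-subject epigenetic age ``A_i = donor_age_i + delta * pgd_i +
  eta_i`` (eta ~ Normal(0, tau^2)): graft biologic age tracks the donor's
  chronologic age, accelerated by ``delta`` years in subjects whose graft
  suffered severe primary graft dysfunction (PGD);
* clock CpGs whose logit-scale betas follow the calibrated age transform of
  an *apparent* age ``s * A_i + c`` — the attenuation ``s`` and offset ``c``
  emulate the systematically "younger" ages a clock trained on other
  tissues reads out in airway epithelium;
* additive logit-scale batch offsets for two array-processing batches;
* promoter CpGs for a synthetic gene catalogue, grouped into named gene
  sets; promoters of genes in the affected sets are hypomethylated by
  ``Delta`` (beta scale) in PGD subjects only;
* CLAD-or-death times from an exponential proportional-hazards model with
  per-year log-hazard ``beta_surv`` on true age, observed from a ~1-year
  brush (left truncation) and administratively censored.

Betas follow a logit-normal model: normal noise on the logit scale keeps
values inside (0, 1) with realistic variance shrinkage near the boundaries.
All draws are reproducible from ``config.seed`` alone; the gene/clock
structure is drawn from a stream that does not depend on which cohort
(study or training) is being generated, so a clock trained on the training
cohort applies to the study cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .clock import transform_age
from .errors import ConfigError
from .io import BetaMatrix, GeneSetCollection, PromoterMap, SampleTable

__all__ = [
    "SimulationConfig",
    "TrueState",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_training_cohort",
]


# plausible pathway names for the synthetic gene-set catalogue; the first
# entries mirror the biology the affected-set default targets
_SET_NAME_POOL = [
    "HALLMARK_HYPOXIA",
    "HALLMARK_TNFA_SIGNALING_VIA_NFKB",
    "HALLMARK_MTORC1_SIGNALING",
    "HALLMARK_IL2_STAT5_SIGNALING",
    "HALLMARK_GLYCOLYSIS",
    "HALLMARK_INFLAMMATORY_RESPONSE",
    "HALLMARK_APOPTOSIS",
    "HALLMARK_E2F_TARGETS",
    "HALLMARK_G2M_CHECKPOINT",
    "HALLMARK_OXIDATIVE_PHOSPHORYLATION",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    Units: ages and ``pgd_acceleration``/``age_noise_sd`` in years,
    ``entry``/``censor`` times in days post-transplant, ``baseline_hazard``
    per day, ``log_hazard_per_year`` per year of true age, CpG noise and
    batch offsets on the logit scale, ``hypomethylation_delta`` on the beta
    scale.
    """

    n_subjects: int = 28
    pgd_fraction: float = 13 / 28
    donor_age_range: tuple[float, float] = (18.0, 65.0)
    recipient_age_range: tuple[float, float] = (25.0, 70.0)
    pgd_acceleration: float = 6.5
    age_noise_sd: float = 8.0

    n_clock_cpgs: int = 761
    age_slope_attenuation: float = 0.38
    age_offset: float = 0.0
    cpg_noise_sd: float = 0.1
    adult_age: float = 20.0

    n_genes: int = 500
    cpgs_per_promoter: int = 3
    promoter_noise_sd: float = 0.4
    n_gene_sets: int = 50
    genes_per_set: int = 25
    affected_set_names: tuple[str, ...] = ("HALLMARK_HYPOXIA",)
    hypomethylation_delta: float = 0.05

    batch_offsets: tuple[float, ...] = (0.0, 0.2)

    baseline_hazard: float = 5e-5
    log_hazard_per_year: float = 0.05
    censor_time: float = 2000.0
    entry_time_range: tuple[float, float] = (360.0, 380.0)

    training_age_range: tuple[float, float] = (1.0, 90.0)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_clock_cpgs < 1 or self.n_genes < 1:
            raise ConfigError("counts must be >= 1")
        if not 0.0 <= self.pgd_fraction <= 1.0:
            raise ConfigError("pgd_fraction must be in [0, 1]")
        if self.promoter_noise_sd < 0:
            raise ConfigError("promoter_noise_sd must be >= 0")
        if self.cpg_noise_sd < 0 or self.age_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.hypomethylation_delta < 0:
            raise ConfigError("hypomethylation_delta must be >= 0")
        if len(self.batch_offsets) < 1:
            raise ConfigError("need at least one batch")
        if self.n_gene_sets < len(self.affected_set_names):
            raise ConfigError(
                "more affected_set_names than gene sets to generate"
            )
        if self.genes_per_set > self.n_genes:
            raise ConfigError("genes_per_set exceeds gene catalogue size")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - {f.name for f in
                              cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("donor_age_range", "recipient_age_range", "batch_offsets",
                    "affected_set_names", "entry_time_range",
                    "training_age_range"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        for k, v in doc.items():
            if isinstance(v, tuple):
                doc[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class TrueState:
    """Ground truth behind a simulated cohort, for recovery tests."""

    epigenetic_age: np.ndarray        # true A_i, years
    clock_cpg_ids: list[str]
    clock_intercepts: np.ndarray      # a_j, logit scale
    clock_slopes: np.ndarray          # b_j, logit scale per transformed year
    affected_sets: list[str]
    affected_genes: list[str]
    batch_offsets: dict[str, float]
    baseline_hazard: float
    log_hazard_per_year: float
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]


class SimulatedCohort(NamedTuple):
    betas: BetaMatrix
    samples: SampleTable
    promoters: PromoterMap
    gene_sets: GeneSetCollection
    truth: TrueState


# ---------------------------------------------------------------------------
# structure shared by training and study cohorts
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class _Structure:
    clock_cpg_ids: list[str]
    clock_a: np.ndarray
    clock_b: np.ndarray
    genes: list[str]
    promoter_cpg_ids: list[str]        # length n_genes * cpgs_per_promoter
    promoter_gene_of_cpg: list[str]
    promoter_a: np.ndarray
    pmap: PromoterMap
    gene_sets: GeneSetCollection
    affected_genes: list[str]


def _build_structure(cfg: SimulationConfig) -> _Structure:
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 17]))

    clock_ids = [f"cgC{j:05d}" for j in range(cfg.n_clock_cpgs)]
    clock_a = rng.normal(-0.2, 1.0, size=cfg.n_clock_cpgs)
    # age slopes: half hyper-, half hypomethylating with age
    mag = rng.uniform(0.5, 1.5, size=cfg.n_clock_cpgs)
    sign = rng.choice([-1.0, 1.0], size=cfg.n_clock_cpgs)
    clock_b = mag * sign

    genes = [f"G{k + 1:04d}" for k in range(cfg.n_genes)]
    # synthetic genome: one chromosome, TSS every 10 kb, strand alternating;
    # promoter window [TSS-1500, TSS+500) strand-aware, 0-based half-open
    rows = []
    prom_cpg_ids: list[str] = []
    prom_gene: list[str] = []
    for k, gene in enumerate(genes):
        tss = 100_000 + k * 10_000
        strand = "+" if k % 2 == 0 else "-"
        if strand == "+":
            start, end = tss - 1500, tss + 500
        else:
            start, end = tss - 500, tss + 1500
        for m in range(cfg.cpgs_per_promoter):
            cpg = f"cgP{k:04d}_{m}"
            prom_cpg_ids.append(cpg)
            prom_gene.append(gene)
            rows.append((cpg, gene, "chr1", start, end, strand))
    pmap = PromoterMap(pd.DataFrame(rows, columns=PromoterMap.COLUMNS))
    prom_a = rng.normal(-0.2, 1.5, size=len(prom_cpg_ids))

    names = list(cfg.affected_set_names)
    for cand in _SET_NAME_POOL:
        if len(names) >= cfg.n_gene_sets:
            break
        if cand not in names:
            names.append(cand)
    idx = 1
    while len(names) < cfg.n_gene_sets:
        cand = f"HALLMARK_SET_{idx:03d}"
        if cand not in names:
            names.append(cand)
        idx += 1
    sets = {
        name: sorted(rng.choice(genes, size=cfg.genes_per_set,
                                replace=False).tolist())
        for name in names
    }
    coll = GeneSetCollection(sets)
    affected = sorted({g for s in cfg.affected_set_names for g in sets[s]})
    return _Structure(clock_ids, clock_a, clock_b, genes, prom_cpg_ids,
                      prom_gene, prom_a, pmap, coll, affected)


def _clock_betas(struct: _Structure, apparent_age: np.ndarray,
                 cfg: SimulationConfig, rng: np.random.Generator,
                 batch_shift: np.ndarray | None = None) -> np.ndarray:
    """Logit-normal clock CpG betas driven by the calibrated transform."""
    f = np.asarray(transform_age(apparent_age, cfg.adult_age), dtype=float)
    logit = struct.clock_a[None, :] + np.outer(f, struct.clock_b)
    if batch_shift is not None:
        logit = logit + batch_shift[:, None]
    if cfg.cpg_noise_sd > 0:
        logit = logit + rng.normal(0.0, cfg.cpg_noise_sd, size=logit.shape)
    return _sigmoid(logit)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a study cohort plus its ground truth.

    Returns betas (clock CpGs then promoter CpGs), the sample sheet,
    the CpG->promoter map, the gene-set catalogue, and a :class:`TrueState`.
    Identical ``config`` (including seed) gives bitwise-identical output.
    """
    cfg = config
    struct = _build_structure(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 29]))

    n = cfg.n_subjects
    n_pgd = int(round(cfg.pgd_fraction * n))
    pgd = np.zeros(n, dtype=bool)
    pgd[rng.permutation(n)[:n_pgd]] = True

    donor_age = rng.uniform(*cfg.donor_age_range, size=n)
    recipient_age = rng.uniform(*cfg.recipient_age_range, size=n)
    eta = (rng.normal(0.0, cfg.age_noise_sd, size=n)
           if cfg.age_noise_sd > 0 else np.zeros(n))
    true_age = donor_age + cfg.pgd_acceleration * pgd + eta
    # the log calibration needs positive ages; resample the rare subject
    # whose noise pushed it at or below zero
    while np.any(true_age <= 0.5):
        bad = true_age <= 0.5
        true_age[bad] = (donor_age[bad] + cfg.pgd_acceleration * pgd[bad]
                         + rng.normal(0.0, cfg.age_noise_sd, int(bad.sum())))

    n_batches = len(cfg.batch_offsets)
    batch_labels = [f"batch{b + 1}" for b in range(n_batches)]
    batch_idx = rng.permutation(np.arange(n) % n_batches)
    batch = np.array([batch_labels[b] for b in batch_idx])
    batch_shift = np.asarray(cfg.batch_offsets, dtype=float)[batch_idx]

    apparent = cfg.age_slope_attenuation * true_age + cfg.age_offset
    clock_vals = _clock_betas(struct, apparent, cfg, rng, batch_shift)

    prom_logit = (struct.promoter_a[None, :]
                  + batch_shift[:, None])
    if cfg.promoter_noise_sd > 0:
        # subject-level biological variation, shared by a promoter's CpGs —
        # this, not probe noise, limits per-promoter testing power
        subj_prom = rng.normal(0.0, cfg.promoter_noise_sd,
                               size=(n, cfg.n_genes))
        prom_logit = prom_logit + np.repeat(subj_prom,
                                            cfg.cpgs_per_promoter, axis=1)
    if cfg.cpg_noise_sd > 0:
        prom_logit = prom_logit + rng.normal(
            0.0, cfg.cpg_noise_sd, size=prom_logit.shape)
    prom_vals = _sigmoid(prom_logit)
    if cfg.hypomethylation_delta > 0 and struct.affected_genes:
        affected_cols = np.array(
            [g in set(struct.affected_genes) for g in struct.promoter_gene_of_cpg]
        )
        shift = np.outer(pgd.astype(float),
                         affected_cols.astype(float)) * cfg.hypomethylation_delta
        prom_vals = np.clip(prom_vals - shift, 0.0, 1.0)

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    values = pd.DataFrame(
        np.hstack([clock_vals, prom_vals]),
        index=sample_ids,
        columns=struct.clock_cpg_ids + struct.promoter_cpg_ids,
    )
    betas = BetaMatrix(values)

    # survival: exponential PH on true age, observed from the brush onward.
    # The exponential hazard is memoryless, so drawing the residual time
    # from entry equals conditioning a time-zero draw on T > entry.
    entry = rng.uniform(*cfg.entry_time_range, size=n).round(0)
    hazard = cfg.baseline_hazard * np.exp(cfg.log_hazard_per_year * true_age)
    t_event = entry + rng.exponential(1.0 / hazard, size=n)
    event = t_event <= cfg.censor_time
    event_time = np.where(event, t_event, cfg.censor_time)

    table = pd.DataFrame({
        "sample_id": sample_ids,
        "donor_age": donor_age,
        "recipient_age": recipient_age,
        "pgd": pgd,
        "batch": batch,
        "donor_sex": rng.choice(["F", "M"], size=n, p=[0.25, 0.75]),
        "recipient_sex": rng.choice(["F", "M"], size=n, p=[0.45, 0.55]),
        "donor_bmi": rng.normal(24.0, 4.0, size=n).clip(15, 45).round(1),
        "recipient_bmi": rng.normal(26.0, 4.5, size=n).clip(15, 45).round(1),
        "donor_white": rng.random(n) < 0.5,
        "recipient_white": rng.random(n) < 0.7,
        "cmv_group": rng.choice(["D-R-", "D-R+", "D+R-", "D+R+"], size=n,
                                p=[0.15, 0.25, 0.28, 0.32]),
        "indication": rng.choice(["A", "C", "D"], size=n,
                                 p=[0.08, 0.17, 0.75]),
        "entry_time": entry,
        "event_time": event_time,
        "event": event,
    })
    samples = SampleTable(table)

    truth = TrueState(
        epigenetic_age=true_age,
        clock_cpg_ids=struct.clock_cpg_ids,
        clock_intercepts=struct.clock_a,
        clock_slopes=struct.clock_b,
        affected_sets=list(cfg.affected_set_names),
        affected_genes=struct.affected_genes,
        batch_offsets=dict(zip(batch_labels, cfg.batch_offsets)),
        baseline_hazard=cfg.baseline_hazard,
        log_hazard_per_year=cfg.log_hazard_per_year,
        config=cfg,
    )
    return SimulatedCohort(betas, samples, struct.pmap, struct.gene_sets, truth)


def simulate_training_cohort(
    config: SimulationConfig, n_train: int, *, subject_seed: int | None = None,
) -> tuple[BetaMatrix, np.ndarray]:
    """Generate a clock-training set from the same CpG structure.

    Training samples carry no PGD effect, no batch shift, and no
    apparent-age attenuation: their clock CpGs follow the calibrated
    transform of the *true* age directly, emulating the source-tissue
    reference panel an external clock is trained on.  ``n_train`` may be
    smaller than the CpG count; the penalized fit handles p > n.
    Returns the beta matrix and the true ages.

    ``subject_seed`` redraws ages and noise while keeping the CpG structure
    fixed — use it to generate held-out sets for the same clock.
    """
    cfg = config
    struct = _build_structure(cfg)
    entropy = ([int(cfg.seed), 43] if subject_seed is None
               else [int(cfg.seed), 43, int(subject_seed)])
    rng = np.random.default_rng(np.random.SeedSequence(entropy))
    ages = rng.uniform(*cfg.training_age_range, size=int(n_train))
    vals = _clock_betas(struct, ages, cfg, rng)
    sample_ids = [f"T{i + 1:04d}" for i in range(int(n_train))]
    betas = BetaMatrix(pd.DataFrame(vals, index=sample_ids,
                                    columns=struct.clock_cpg_ids))
    return betas, ages
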