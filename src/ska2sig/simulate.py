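"""Synthetic methylation cohorts with the structure the analysis assumes.

The generator emulates a multicohort suicide-biomarker study: a postmortem
prefrontal-cortex-neuron discovery cohort (cases vs controls, N = 45 with 22
cases by default, matching the study design this package targets), plus
peripheral blood/saliva cohorts whose methylation is a cell-type mixture
with a planted latent "biosignature" factor.

Planted structure, by cohort type:

* Brain: a subset of probes carries a case x SKA2-methylation interaction —
  probe beta = baseline + a*case + b*ska2m + c*(case*ska2m) + noise, with
  c = ``interaction_effect_size`` on planted probes and 0 elsewhere. SKA2
  (rs7208505) genotype is drawn from Hardy-Weinberg; the CpG methylation
  value exists only on CpG-preserving alleles (genotype >= 1).
* Peripheral: observed beta = sum_k w_k * reference_k + loading * latent
  (biosignature probes only) + noise, clipped to [0, 1). Cell weights w are
  Dirichlet; the per-sample latent factor is constructed to correlate
  (negatively, by default) with the myeloid fraction (granulocyte +
  monocyte weight). Suicidal-ideation/attempt outcomes follow a logistic
  model in the SKA2 fields and the latent factor; cortisol, IL-6, CTQ and
  perceived-stress phenotypes have configurable linear links to the latent
  factor.

The planted biosignature probes are a subset of the planted interaction
probes, so the discovery pipeline (brain screen -> AUC filter -> PCA) has a
recoverable ground truth. Every bundle records the exact latent factor and
per-probe truth flags used during generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import BetaMatrix, MethylationError
from .deconvolution import CellReference

__all__ = [
    "SimulationConfig",
    "CohortBundle",
    "MulticohortStudy",
    "generate_cell_reference",
    "generate_brain_cohort",
    "generate_peripheral_cohort",
    "generate_multicohort_study",
    "DEFAULT_CELL_TYPES",
]

# leukocyte types of the Houseman blood reference
DEFAULT_CELL_TYPES = ("cd8t", "cd4t", "bcell", "nk", "monocyte", "granulocyte")

MAX_BETA = 1.0 - 1e-9  # BetaMatrix requires values strictly below 1


def _default_dirichlet():
    # concentration ~ typical whole-blood composition (granulocytes dominant)
    return {"cd8t": 4.0, "cd4t": 8.0, "bcell": 2.0, "nk": 2.0,
            "monocyte": 4.0, "granulocyte": 20.0}


def _default_outcome_model():
    return {"intercept": -1.2, "ska2_methylation": 1.0, "ska2_genotype": 0.3,
            "biosignature": 1.8, "ska2_x_biosignature": 0.8}


def _default_hpa_model():
    # post-stress cortisol AUC: biosignature x childhood-trauma interaction
    return {"intercept": 900.0, "biosignature": 60.0, "ctq": -6.0,
            "biosignature_x_ctq": -2.0, "noise_sd": 150.0}


def _default_peripheral_sizes():
    # validation size mirrors the largest trauma-cohort blood set (N = 376);
    # the training cohort is enlarged beyond the tiny real training sets so
    # the AUC filter is stable on synthetic data
    return {"train_blood": 120, "saliva": 80, "validation_blood": 376}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_probes: int = 20_000
    n_brain_samples: int = 45
    brain_case_fraction: float = 22 / 45
    peripheral_sizes: dict = field(default_factory=_default_peripheral_sizes)
    n_planted_interaction_probes: int = 100
    n_biosignature_probes: int = 72
    interaction_effect_size: float = 0.15
    case_main_effect: float = 0.01
    ska2_main_effect: float = 0.05
    biosignature_loading_mean: float = 0.06
    biosignature_loading_sd: float = 0.015
    probe_noise_sd: float = 0.02
    dirichlet_concentration: dict = field(default_factory=_default_dirichlet)
    outcome_model: dict = field(default_factory=_default_outcome_model)
    myeloid_biosignature_correlation: float = -0.6
    ska2_allele_frequency: float = 0.6
    hpa_model: dict = field(default_factory=_default_hpa_model)
    il6_detection_limit: float = 0.5
    reference_separation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0 or self.n_brain_samples <= 0:
            raise MethylationError("counts must be positive")
        if self.n_planted_interaction_probes > self.n_probes:
            raise MethylationError("planted probes exceed probe universe")
        if self.n_biosignature_probes > self.n_planted_interaction_probes:
            raise MethylationError(
                "biosignature probes must be a subset of planted interaction probes"
            )
        if self.probe_noise_sd <= 0:
            raise MethylationError("noise sd must be positive")
        if any(v <= 0 for v in self.dirichlet_concentration.values()):
            raise MethylationError("Dirichlet concentrations must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class CohortBundle:
    """A generated cohort plus its ground truth."""

    name: str
    beta: BetaMatrix
    samples: pd.DataFrame          # phenotype sheet, indexed by sample_id
    probe_truth: pd.DataFrame      # planted_interaction / planted_biosignature flags
    latent: pd.Series              # the latent biosignature factor, as generated
    clip_fraction: float = 0.0
    seed: int | None = None


class MulticohortStudy(dict):
    """Mapping of cohort name -> CohortBundle, with the shared cell reference."""

    def __init__(self, cohorts: dict, reference: CellReference,
                 config: SimulationConfig):
        super().__init__(cohorts)
        self.reference = reference
        self.config = config


def _probe_ids(n: int) -> list:
    return [f"cg{i:08d}" for i in range(n)]


def _clip_beta(x: np.ndarray) -> tuple[np.ndarray, float]:
    clipped = np.clip(x, 0.0, MAX_BETA)
    frac = float(np.mean((x < 0.0) | (x > MAX_BETA)))
    return clipped, frac


def _draw_ska2(rng: np.random.Generator, n: int, allele_freq: float):
    """Hardy-Weinberg genotype (count of CpG-preserving alleles) and CpG beta."""
    p = allele_freq
    genotype = rng.choice([0, 1, 2], size=n, p=[(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    meth = np.where(genotype >= 1, rng.uniform(0.1, 0.9, size=n), np.nan)
    return genotype, meth


def _biosignature_loadings(config: SimulationConfig) -> pd.Series:
    """Per-probe latent-factor loadings, shared by every cohort of a study.

    Drawn from a dedicated stream keyed on the master seed (not the cohort
    seed) so the planted factor structure is identical across cohorts —
    without this a model trained in one cohort could not transfer.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x51A2]))
    ids = _probe_ids(config.n_probes)[: config.n_biosignature_probes]
    loadings = rng.normal(config.biosignature_loading_mean,
                          config.biosignature_loading_sd, size=len(ids))
    loadings *= rng.choice([-1.0, 1.0], size=len(ids))
    return pd.Series(loadings, index=ids)


def _probe_truth_frame(probe_ids, planted, biosig, effect, loadings=None):
    truth = pd.DataFrame(index=probe_ids)
    truth["planted_interaction"] = [p in planted for p in probe_ids]
    truth["planted_biosignature"] = [p in biosig for p in probe_ids]
    truth["interaction_coef"] = np.where(truth["planted_interaction"], effect, 0.0)
    truth["biosignature_loading"] = 0.0
    if loadings is not None:
        shared = [p for p in loadings.index if p in truth.index]
        truth.loc[shared, "biosignature_loading"] = loadings.loc[shared]
    return truth


def generate_cell_reference(
    n_loci: int,
    cell_types=DEFAULT_CELL_TYPES,
    seed: int = 0,
    separation: float = 0.2,
    probe_ids=None,
) -> CellReference:
    """Random cell-type mean-methylation reference with distinguishable columns.

    Every pair of cell types must differ by at least ``separation`` in mean
    absolute beta over loci, otherwise an error is raised (independent
    uniform profiles give ~0.3, so the default is comfortably achievable).
    """
    if len(cell_types) < 2 or n_loci < 2:
        raise MethylationError("need >= 2 cell types and >= 2 loci")
    rng = np.random.default_rng(seed)
    profile = rng.uniform(0.05, 0.95, size=(n_loci, len(cell_types)))
    ids = list(probe_ids) if probe_ids is not None else _probe_ids(n_loci)
    if len(ids) != n_loci:
        raise MethylationError("probe_ids length must equal n_loci")
    ref = CellReference(pd.DataFrame(profile, index=ids, columns=list(cell_types)))
    for i, a in enumerate(cell_types):
        for b in list(cell_types)[i + 1:]:
            d = float(np.abs(ref.profile[a] - ref.profile[b]).mean())
            if d < separation:
                raise MethylationError(
                    f"cell types {a!r} and {b!r} separated by only {d:.3f} "
                    f"(< {separation}); increase loci or lower separation"
                )
    return ref


def generate_brain_cohort(config: SimulationConfig, seed=None,
                          name: str = "brain") -> CohortBundle:
    """Postmortem neuron cohort with the planted case x SKA2-methylation interaction."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = config.n_brain_samples
    n_cases = int(round(config.brain_case_fraction * n))
    if n_cases == 0 or n_cases == n:
        raise MethylationError("brain cohort needs both cases and controls")

    probe_ids = _probe_ids(config.n_probes)
    planted = set(probe_ids[: config.n_planted_interaction_probes])
    biosig = set(probe_ids[: config.n_biosignature_probes])

    case = np.zeros(n)
    case[:n_cases] = 1.0
    age = rng.normal(45.0, 12.0, size=n).clip(18, 90)
    sex = rng.integers(0, 2, size=n).astype(float)
    genotype, ska2m = _draw_ska2(rng, n, config.ska2_allele_frequency)
    ska2m_filled = np.nan_to_num(ska2m, nan=0.0)

    baseline = rng.uniform(0.15, 0.85, size=config.n_probes)
    noise = rng.normal(0.0, config.probe_noise_sd, size=(config.n_probes, n))
    values = baseline[:, None] + noise
    idx_planted = np.arange(config.n_planted_interaction_probes)
    a, b, c = (config.case_main_effect, config.ska2_main_effect,
               config.interaction_effect_size)
    values[idx_planted] += (a * case + b * ska2m_filled
                            + c * case * ska2m_filled)[None, :]
    values, clip_frac = _clip_beta(values)

    sample_ids = [f"{name}_s{i:03d}" for i in range(n)]
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "age": age,
        "sex": sex,
        "tissue": "brain_neuron",
        "suicide_death": case.astype(int),
        "ska2_genotype": genotype,
        "ska2_methylation": ska2m,
    }).set_index("sample_id", drop=False)

    return CohortBundle(
        name=name,
        beta=BetaMatrix.from_arrays(values, probe_ids, sample_ids),
        samples=samples,
        probe_truth=_probe_truth_frame(probe_ids, planted, biosig, c,
                                       loadings=_biosignature_loadings(config)),
        latent=pd.Series(np.zeros(n), index=sample_ids),
        clip_fraction=clip_frac,
        seed=seed,
    )


def generate_peripheral_cohort(
    config: SimulationConfig,
    reference: CellReference,
    probe_set=None,
    n_samples: int | None = None,
    seed=None,
    name: str = "peripheral",
    tissue: str = "blood",
) -> CohortBundle:
    """Peripheral cohort: cell mixture + latent biosignature + phenotypes."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = n_samples if n_samples is not None else 120

    probe_ids = (list(probe_set) if probe_set is not None
                 else _probe_ids(config.n_probes))
    probe_id_set = set(probe_ids)
    ref_loci = set(reference.loci)
    biosig_ids = [p for p in _probe_ids(config.n_probes)
                  [: config.n_biosignature_probes] if p in probe_id_set]
    missing_ref = [p for p in probe_ids if p not in ref_loci]
    if missing_ref:
        raise MethylationError(
            f"reference does not cover {len(missing_ref)} requested probes"
        )

    cell_types = reference.cell_types
    conc = np.array([config.dirichlet_concentration.get(ct, 1.0)
                     for ct in cell_types])
    if (conc <= 0).any():
        raise MethylationError("Dirichlet concentrations must be positive")
    weights = rng.dirichlet(conc, size=n)  # rows sum to 1 exactly

    myeloid = np.zeros(n)
    for ct in ("granulocyte", "monocyte"):
        if ct in cell_types:
            myeloid += weights[:, cell_types.index(ct)]
    # latent factor with target correlation to the myeloid fraction
    rho = config.myeloid_biosignature_correlation
    z_myeloid = (myeloid - myeloid.mean()) / max(myeloid.std(), 1e-12)
    latent = rho * z_myeloid + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(size=n)

    ref_mat = reference.profile.loc[probe_ids].to_numpy()
    values = ref_mat @ weights.T
    loadings = _biosignature_loadings(config).loc[biosig_ids].to_numpy()
    index_of = {p: i for i, p in enumerate(probe_ids)}
    pos = [index_of[p] for p in biosig_ids]
    values[pos] += np.outer(loadings, latent)
    values += rng.normal(0.0, config.probe_noise_sd, size=values.shape)
    values, clip_frac = _clip_beta(values)

    genotype, ska2m = _draw_ska2(rng, n, config.ska2_allele_frequency)
    ska2m_filled = np.nan_to_num(ska2m, nan=0.0)
    om = config.outcome_model
    lp = (om["intercept"] + om["ska2_methylation"] * ska2m_filled
          + om["ska2_genotype"] * genotype + om["biosignature"] * latent
          + om["ska2_x_biosignature"] * ska2m_filled * latent)
    p_event = 1.0 / (1.0 + np.exp(-lp))
    ideation = (rng.uniform(size=n) < p_event).astype(int)
    attempt = (rng.uniform(size=n) < p_event).astype(int)

    ctq = rng.gamma(shape=4.0, scale=8.0, size=n) + 25.0  # CTQ totals, floor 25
    hpa = config.hpa_model
    cortisol_post = (hpa["intercept"] + hpa["biosignature"] * latent
                     + hpa["ctq"] * ctq + hpa["biosignature_x_ctq"] * latent * ctq
                     + rng.normal(0.0, hpa["noise_sd"], size=n))
    cortisol_auc = 800.0 + 80.0 * latent + rng.normal(0.0, 120.0, size=n)
    dst_day2 = np.exp(1.0 - 0.4 * latent + rng.normal(0.0, 0.5, size=n))
    il6_raw = np.exp(0.3 + 0.5 * latent + rng.normal(0.0, 0.6, size=n))
    il6 = np.where(il6_raw < config.il6_detection_limit, 0.0, il6_raw)
    stress = 15.0 + 4.0 * latent + rng.normal(0.0, 4.0, size=n)

    sample_ids = [f"{name}_s{i:03d}" for i in range(n)]
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "age": rng.normal(35.0, 10.0, size=n).clip(18, 80),
        "sex": rng.integers(0, 2, size=n).astype(float),
        "tissue": tissue,
        "suicidal_ideation": ideation,
        "suicide_attempt": attempt,
        "ska2_genotype": genotype,
        "ska2_methylation": ska2m,
        "ctq": ctq,
        "cortisol_auc": cortisol_auc,
        "cortisol_auc_posttest": cortisol_post,
        "dst_day2_cortisol": dst_day2,
        "il6": il6,
        "perceived_stress": stress,
        "ptsd": rng.integers(0, 2, size=n),
        "substance_use": (rng.uniform(size=n) < 0.25).astype(int),
    }).set_index("sample_id", drop=False)
    for i, ct in enumerate(cell_types):
        samples[f"prop_{ct}"] = weights[:, i]
    samples["myeloid_true"] = myeloid

    all_ids = _probe_ids(config.n_probes)
    planted = set(all_ids[: config.n_planted_interaction_probes])
    truth = _probe_truth_frame(probe_ids, planted, set(biosig_ids),
                               config.interaction_effect_size,
                               loadings=_biosignature_loadings(config))
    return CohortBundle(
        name=name,
        beta=BetaMatrix.from_arrays(values, probe_ids, sample_ids),
        samples=samples,
        probe_truth=truth,
        latent=pd.Series(latent, index=sample_ids),
        clip_fraction=clip_frac,
        seed=seed,
    )


def generate_multicohort_study(config: SimulationConfig) -> MulticohortStudy:
    """One brain discovery cohort plus peripheral cohorts on a shared probe universe.

    Per-cohort seeds are derived deterministically from the master seed, so
    the whole study is reproducible from ``config.seed`` alone.
    """
    names = ["brain"] + list(config.peripheral_sizes)
    if len(set(names)) != len(names):
        raise MethylationError(f"duplicate cohort names in {names}")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(names) + 1)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]

    reference = generate_cell_reference(
        config.n_probes, DEFAULT_CELL_TYPES, seed=seeds[0],
        separation=config.reference_separation,
    )
    cohorts = {"brain": generate_brain_cohort(config, seed=seeds[1])}
    for i, (cname, size) in enumerate(config.peripheral_sizes.items()):
        tissue = "saliva" if "saliva" in cname else "blood"
        cohorts[cname] = generate_peripheral_cohort(
            config, reference, n_samples=size, seed=seeds[2 + i],
            name=cname, tissue=tissue,
        )
    return MulticohortStudy(cohorts, reference, config)
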