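"""Synthetic methylome generator.

Emulates the statistical structure of cervical-smear methylation cohorts:
per-CpG, per-cell-type beta distributions; per-sample convex mixtures of
epithelial / fibroblast / immune / tumour DNA; a case/control shift confined
to one compartment at a subset of CpGs; optional age trend; array-like
measurement noise and detection failures.  Every downstream stage of the
pipeline is testable against the ground truth returned here.

Beta matrices are pandas DataFrames with CpG ids as the index and sample ids
as columns; annotation is a separate DataFrame keyed by ``cpg_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_TYPES = ("epithelial", "fibroblast", "immune", "tumour")

#: EPIC-like skew of relation-to-CpG-island classes.
DEFAULT_REGION_PROPORTIONS = {"Island": 0.20, "Shore": 0.25, "Shelf": 0.10, "OpenSea": 0.45}

__all__ = [
    "CELL_TYPES",
    "DEFAULT_REGION_PROPORTIONS",
    "EffectSpec",
    "SimulationTruth",
    "UniformICFractions",
    "DirichletFractions",
    "generate_profiles",
    "generate_cohort",
    "generate_reference_samples",
]


@dataclass(frozen=True)
class EffectSpec:
    """A planted case/control shift carried by one cell-type compartment."""

    informative_cpgs: tuple
    epithelial_delta: float
    compartment: str = "epithelial"

    def __post_init__(self) -> None:
        if not -1 < self.epithelial_delta < 1:
            raise ValueError("epithelial_delta must lie in (-1, 1)")
        if self.compartment not in CELL_TYPES:
            raise ValueError(f"compartment must be one of {CELL_TYPES}")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort."""

    fractions: pd.DataFrame  # sample x cell type, rows sum to 1
    epithelial_delta: pd.Series  # per-CpG true epithelial-compartment delta-beta
    immune_delta: pd.Series
    informative_cpgs: tuple
    seed: int
    component_draws: dict | None = None  # cell type -> CpG x sample draws (optional)

    def __post_init__(self) -> None:
        s = self.fractions[list(CELL_TYPES)].sum(axis=1).to_numpy()
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValueError("true cell fractions must sum to 1 within 1e-9")


class UniformICFractions:
    """Immune fraction uniform on [low, high]; fibroblast a small Beta share.

    The immune marginal spans a wide range so that regressions of beta on the
    immune fraction are well conditioned; the remainder is split between a
    small fibroblast share and epithelium, the dominant smear component.
    """

    def __init__(self, low: float = 0.0, high: float = 0.8,
                 fibroblast_a: float = 2.0, fibroblast_b: float = 18.0):
        if not 0 <= low < high <= 1:
            raise ValueError("need 0 <= low < high <= 1")
        self.low, self.high = low, high
        self.fibroblast_a, self.fibroblast_b = fibroblast_a, fibroblast_b

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        ic = rng.uniform(self.low, self.high, n)
        fib = (1 - ic) * rng.beta(self.fibroblast_a, self.fibroblast_b, n)
        epi = 1 - ic - fib
        return np.column_stack([epi, fib, ic, np.zeros(n)])


class DirichletFractions:
    """Dirichlet draw over (epithelial, fibroblast, immune); tumour 0."""

    def __init__(self, alpha=(6.0, 1.0, 3.0)):
        self.alpha = tuple(alpha)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        f = rng.dirichlet(self.alpha, n)
        return np.column_stack([f, np.zeros(n)])


def _shape_params(mean: np.ndarray, precision: np.ndarray):
    return mean * precision, (1 - mean) * precision


def generate_profiles(
    n_cpgs: int,
    seed: int,
    annotation_spec: dict | None = None,
    markers_per_type: int | None = None,
    marker_high: float = 0.90,
    marker_low: float = 0.10,
):
    """Per-cell-type beta-distribution profiles plus a CpG annotation table.

    Each CpG gets one Beta(a, b) profile per cell type.  A designated marker
    subset per cell type separates that type's mean beta from every other
    type by at least 0.5, which is what reference-panel construction and
    deconvolution exploit.  Annotation assigns each CpG a relation-to-island
    class with the requested proportions (EPIC-like skew by default).

    Returns ``(profiles, annotation)``: profiles has one row per
    (cpg_id, cell_type) with columns ``a`` and ``b``; annotation has one row
    per CpG with chromosome, position, region class and a gene label.
    """
    if n_cpgs < 10:
        raise ValueError("n_cpgs must be at least 10")
    props = dict(annotation_spec or DEFAULT_REGION_PROPORTIONS)
    if abs(sum(props.values()) - 1) > 1e-8:
        raise ValueError("region-class proportions must sum to 1")
    if markers_per_type is None:
        markers_per_type = max(1, n_cpgs // 50)
    if 4 * markers_per_type > n_cpgs:
        raise ValueError("too many markers for the number of CpGs")

    rng = np.random.default_rng(seed)
    cpg_ids = np.array([f"cg{i:07d}" for i in range(n_cpgs)])

    # bimodal background methylome: mostly hypo- or hyper-methylated CpGs
    comp = rng.choice(3, n_cpgs, p=[0.4, 0.4, 0.2])
    base = np.where(
        comp == 0, rng.beta(2, 12, n_cpgs), np.where(comp == 1, rng.beta(12, 2, n_cpgs), rng.beta(3, 3, n_cpgs))
    )
    base = np.clip(base, 0.05, 0.95)

    means = np.empty((n_cpgs, len(CELL_TYPES)))
    for j in range(len(CELL_TYPES)):
        means[:, j] = np.clip(base + rng.normal(0, 0.03, n_cpgs), 0.03, 0.97)

    # planted markers: the owning type sits on one side of the scale, all
    # other types on the far side, giving a mean separation >= 0.5
    marker_ids = rng.choice(n_cpgs, size=4 * markers_per_type, replace=False)
    marker_type = np.repeat(np.arange(4), markers_per_type)
    hypo = rng.random(4 * markers_per_type) < 0.5
    for idx, t, lo_side in zip(marker_ids, marker_type, hypo):
        own = marker_low if lo_side else marker_high
        other = marker_high if lo_side else marker_low
        jit = rng.uniform(-0.02, 0.02, 4)
        means[idx, :] = other + jit
        means[idx, t] = own + jit[t]

    precision = rng.lognormal(mean=np.log(120.0), sigma=0.4, size=(n_cpgs, len(CELL_TYPES)))
    a, b = _shape_params(means, precision)

    profiles = pd.DataFrame(
        {
            "cpg_id": np.repeat(cpg_ids, len(CELL_TYPES)),
            "cell_type": np.tile(CELL_TYPES, n_cpgs),
            "a": a.ravel(),
            "b": b.ravel(),
            "is_marker": False,
        }
    )
    flat_marker = marker_ids * len(CELL_TYPES) + marker_type
    profiles.loc[flat_marker, "is_marker"] = True

    classes = list(props)
    counts = np.floor(np.array([props[c] for c in classes]) * n_cpgs).astype(int)
    counts[-1] += n_cpgs - counts.sum()
    region = rng.permutation(np.repeat(classes, counts))
    annotation = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "chromosome": rng.choice([f"chr{i}" for i in range(1, 23)], n_cpgs),
            "position": np.sort(rng.choice(np.arange(1, 10**8), n_cpgs, replace=False)),
            "region_class": region,
            "gene": [f"GENE{i // 5:05d}" for i in range(n_cpgs)],
        }
    )
    return profiles, annotation


def feasible_effect_cpgs(
    profiles: pd.DataFrame,
    delta: float,
    compartment: str = "epithelial",
    margin: float = 0.02,
) -> np.ndarray:
    """CpG ids whose compartment mean stays inside (margin, 1-margin) after a shift.

    Convenience for planting effects: a signed shift is only admissible where
    the shifted Beta mean remains a valid proportion.
    """
    sub = profiles[profiles["cell_type"] == compartment]
    mean = (sub["a"] / (sub["a"] + sub["b"])).to_numpy()
    ok = (mean + delta > margin) & (mean + delta < 1 - margin)
    return sub.loc[ok, "cpg_id"].to_numpy()


def _profile_arrays(profiles: pd.DataFrame):
    """(cpg_ids, dict cell_type -> (a, b) arrays aligned to cpg order)."""
    wide_a = profiles.pivot(index="cpg_id", columns="cell_type", values="a")
    wide_b = profiles.pivot(index="cpg_id", columns="cell_type", values="b")
    cpgs = wide_a.index.to_numpy()
    types = [t for t in CELL_TYPES if t in wide_a.columns]
    return cpgs, types, {t: (wide_a[t].to_numpy(), wide_b[t].to_numpy()) for t in types}


def _shifted_shapes(a: np.ndarray, b: np.ndarray, delta: float, where: np.ndarray):
    mean = a / (a + b)
    prec = a + b
    new_mean = mean.copy()
    new_mean[where] = mean[where] + delta
    if np.any((new_mean[where] <= 0) | (new_mean[where] >= 1)):
        raise ValueError("effect shift pushes a compartment mean outside (0, 1)")
    return new_mean * prec, (1 - new_mean) * prec


def generate_cohort(
    profiles: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    effect: EffectSpec | None = None,
    fraction_model=None,
    tumour_contamination=None,
    noise_sd: float = 0.02,
    detection_fail_rate: float = 1e-5,
    p_thresh: float = 0.01,
    age_range: tuple = (30.0, 75.0),
    seed: int = 0,
    keep_component_draws: bool = False,
):
    """Simulate a case/control cohort of heterogeneous methylomes.

    Each observed beta is a convex combination of sample-specific draws from
    the per-cell-type Beta distributions, weighted by the sample's true cell
    fractions, plus truncated Gaussian measurement noise clipped to [0, 1].
    Cases receive the compartment shift of ``effect`` at its informative
    CpGs.  ``tumour_contamination`` (scalar or per-sample array of the
    tumour proportion rho) replaces rho of every non-tumour compartment.

    Returns ``(beta, sample_sheet, detection_p, truth)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 <= detection_fail_rate <= 1:
        raise ValueError("detection_fail_rate must lie in [0, 1]")
    n = n_cases + n_controls
    cpgs, types, shapes = _profile_arrays(profiles)
    n_cpgs = len(cpgs)
    fraction_model = fraction_model or UniformICFractions()

    # independent streams so that unused components (e.g. tumour at rho=0)
    # never perturb the others
    ss = np.random.SeedSequence(seed)
    r_frac, r_epi, r_fib, r_imm, r_tum, r_noise, r_det, r_sheet = (
        np.random.default_rng(s) for s in ss.spawn(8)
    )
    type_rngs = {"epithelial": r_epi, "fibroblast": r_fib, "immune": r_imm, "tumour": r_tum}

    fractions = fraction_model.draw(n, r_frac)  # epi, fib, imm, tum
    if tumour_contamination is not None:
        rho = np.broadcast_to(np.asarray(tumour_contamination, dtype=float), (n,)).copy()
        if np.any((rho < 0) | (rho > 1)):
            raise ValueError("tumour contamination rho must lie in [0, 1]")
        fractions[:, :3] *= (1 - rho)[:, None]
        fractions[:, 3] = fractions[:, 3] * (1 - rho) + rho

    sample_ids = np.array(
        [f"case{i:04d}" for i in range(n_cases)] + [f"ctrl{i:04d}" for i in range(n_controls)]
    )
    is_case = np.arange(n) < n_cases

    cpg_index = pd.Index(cpgs, name="cpg_id")
    informative_mask = np.zeros(n_cpgs, dtype=bool)
    if effect is not None:
        informative_mask = cpg_index.isin(effect.informative_cpgs)
        if informative_mask.sum() != len(set(effect.informative_cpgs)):
            raise ValueError("effect names CpGs absent from the profiles")

    observed = np.zeros((n_cpgs, n))
    draws_kept: dict = {}
    for j, t in enumerate(CELL_TYPES):
        if t not in types:
            continue
        a, b = shapes[t]
        frac = fractions[:, j]
        rng_t = type_rngs[t]
        if t == "tumour" and np.all(frac == 0):
            continue  # stream untouched: identical output to a tumour-free run
        draw = rng_t.beta(a[:, None], b[:, None], size=(n_cpgs, n))
        if effect is not None and t == effect.compartment and informative_mask.any():
            a_s, b_s = _shifted_shapes(a, b, effect.epithelial_delta, informative_mask)
            case_cols = np.where(is_case)[0]
            shifted = rng_t.beta(
                a_s[informative_mask, None], b_s[informative_mask, None],
                size=(informative_mask.sum(), len(case_cols)),
            )
            draw[np.ix_(informative_mask, case_cols)] = shifted
        observed += frac[None, :] * draw
        if keep_component_draws:
            draws_kept[t] = draw

    if noise_sd > 0:
        observed = np.clip(observed + r_noise.normal(0, noise_sd, observed.shape), 0.0, 1.0)

    # detection p-values: passes well under the threshold, failures above it
    fails = r_det.random(observed.shape) < detection_fail_rate
    detection_p = np.where(fails, r_det.uniform(2 * p_thresh, 1.0, observed.shape),
                           r_det.uniform(0.0, 0.9 * p_thresh, observed.shape))

    ages = r_sheet.uniform(*age_range, n)
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "type": np.where(is_case, "case", "control"),
            "age": np.round(ages, 1),
            "menopausal": np.where(ages >= 51, "post", "pre"),
            "centre": r_sheet.choice(["C1", "C2", "C3"], n),
        }
    )
    beta = pd.DataFrame(observed, index=cpg_index, columns=sample_ids)
    detection = pd.DataFrame(detection_p, index=cpg_index, columns=sample_ids)

    epi_delta = pd.Series(0.0, index=cpg_index, name="epithelial_delta")
    if effect is not None and effect.compartment == "epithelial":
        epi_delta[informative_mask] = effect.epithelial_delta
    truth = SimulationTruth(
        fractions=pd.DataFrame(fractions, index=sample_ids, columns=list(CELL_TYPES)),
        epithelial_delta=epi_delta,
        immune_delta=pd.Series(0.0, index=cpg_index, name="immune_delta"),
        informative_cpgs=tuple(cpg_index[informative_mask]),
        seed=seed,
        component_draws=draws_kept or None,
    )
    return beta, sheet, detection, truth


def generate_reference_samples(profiles: pd.DataFrame, n_per_type: int, seed: int):
    """Pure cell-type samples drawn from each type's Beta profiles.

    Stands in for purified-cell / cell-line reference methylomes.  Returns
    ``(beta, labels)`` with ``n_per_type`` samples per cell type.
    """
    if n_per_type < 2:
        raise ValueError("need at least 2 samples per cell type for rank tests")
    cpgs, types, shapes = _profile_arrays(profiles)
    rng = np.random.default_rng(seed)
    cols, labels, blocks = [], [], []
    for t in types:
        a, b = shapes[t]
        blocks.append(rng.beta(a[:, None], b[:, None], size=(len(cpgs), n_per_type)))
        cols += [f"{t}_{i:03d}" for i in range(n_per_type)]
        labels += [t] * n_per_type
    beta = pd.DataFrame(np.hstack(blocks), index=pd.Index(cpgs, name="cpg_id"), columns=cols)
    return beta, pd.Series(labels, index=cols, name="cell_type")
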