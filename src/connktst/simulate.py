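"""Synthetic two-class, two-modality connectome generator.

Emulates the acallosal-mouse study design: 50 brain regions split into two
hemispheres, a structural connectome of streamline-count-like weights
(dense within each hemisphere, a bundle of strong homotopic "callosal"
edges plus sparse other inter-hemispheric edges), and a functional
connectome obtained as the sample Pearson correlation matrix of a finite
resting-state time series drawn from a latent covariance with matching
block structure.

The condition ("class B") removes a fraction of inter-hemispheric coupling:
structural inter-hemispheric weights are scaled by ``1 - delta_s`` and
inter-hemispheric covariance entries by ``1 - delta_f`` before subject-level
noise.  ``delta_s = 1`` is the full callosal-agenesis analogue;
``delta_s = delta_f = 0`` makes the two classes draws from one distribution
(the exact null).  Known effect sizes make the generator the calibration
and power harness for every statistic in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np
import pandas as pd

from .common_space import mmd_sf_test
from .graphs import BrainGraph, LabeledGraphDataset, Modality, threshold_positive
from .ktst import ktst_test

#: Class labels used for the simulated condition and control groups.
CLASS_A, CLASS_B = "control", "condition"


@dataclass(frozen=True)
class SimulationParams:
    """Study-design parameters of the synthetic generator.

    Defaults mirror the emulated study: 50 nodes, 8+8 structural and 10+10
    functional subjects, 360 functional time points; the condition removes
    60% of inter-hemispheric structural coupling but only 10% of the
    functional coupling (strong structural, mild functional effect).
    """

    l: int = 50
    n_per_class_structural: int = 8
    n_per_class_functional: int = 10
    delta_s: float = 0.6
    delta_f: float = 0.1
    structural_noise: float = 0.3
    functional_timepoints: int = 360
    hemisphere_block: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.l < 4 or self.l % 2:
            raise ValueError("l must be an even integer >= 4")
        if self.n_per_class_structural < 2 or self.n_per_class_functional < 2:
            raise ValueError("need >= 2 subjects per class per modality")
        for name in ("delta_s", "delta_f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.structural_noise < 0:
            raise ValueError("structural_noise must be >= 0")
        if self.functional_timepoints < self.l + 2:
            raise ValueError(
                "functional_timepoints must exceed the node count for a "
                "full-rank sample correlation"
            )
        if not 0.0 < self.hemisphere_block < 1.0:
            raise ValueError("hemisphere_block must be in (0, 1)")


def node_labels(params: SimulationParams) -> tuple[str, ...]:
    """Region labels: L01..Lh for the left hemisphere, R01.. for the right."""
    h = int(round(params.l * params.hemisphere_block))
    return tuple(
        f"L{i + 1:02d}" for i in range(h)
    ) + tuple(f"R{i + 1:02d}" for i in range(params.l - h))


def _hemisphere_masks(params: SimulationParams):
    l = params.l
    h = int(round(l * params.hemisphere_block))
    left = np.zeros(l, dtype=bool)
    left[:h] = True
    inter = left[:, None] ^ left[None, :]
    homotopic = np.zeros((l, l), dtype=bool)
    for i in range(min(h, l - h)):
        homotopic[i, h + i] = homotopic[h + i, i] = True
    return left, inter, homotopic


def _nearest_unit_diagonal_pd(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Diagonal-load until the smallest eigenvalue clears ``floor``, then
    renormalize to unit diagonal."""
    R = (R + R.T) / 2.0
    lam = np.linalg.eigvalsh(R)[0]
    if lam < floor:
        R = R + (floor - lam) * np.eye(R.shape[0])
    d = np.sqrt(np.diagonal(R))
    return R / np.outer(d, d)


def make_base_connectomes(
    params: SimulationParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-A population templates: structural counts and latent covariance.

    The structural base is a symmetric nonnegative matrix of rounded
    log-normal streamline counts: every within-hemisphere pair connected
    (median ~50 streamlines), homotopic inter-hemispheric pairs strongly
    connected (median ~200, the callosal bundle), and a sparse ~10% of the
    remaining inter-hemispheric pairs weakly connected (median ~20).  The
    functional latent covariance is a unit-diagonal positive definite matrix
    with the same block structure: baseline within-hemisphere correlation
    0.3, homotopic correlation 0.6, other inter-hemispheric 0.1.
    """
    rng = np.random.default_rng(params.seed)
    l = params.l
    left, inter, homotopic = _hemisphere_masks(params)
    iu = np.triu_indices(l, k=1)

    within = ~inter
    base = np.zeros((l, l))
    for mask, log_median, log_sd in (
        (within, np.log(50.0), 1.0),
        (homotopic, np.log(200.0), 0.5),
    ):
        sel = mask[iu]
        vals = rng.lognormal(log_median, log_sd, size=int(sel.sum()))
        row = np.zeros(len(iu[0]))
        row[sel] = vals
        base[iu] += row
    other_inter = inter & ~homotopic
    sel = other_inter[iu]
    present = rng.random(int(sel.sum())) < 0.1
    vals = np.where(present, rng.lognormal(np.log(20.0), 1.0, size=len(present)), 0.0)
    row = np.zeros(len(iu[0]))
    row[sel] = vals
    base[iu] += row
    base = np.round(base)
    base = base + base.T
    np.fill_diagonal(base, 0.0)

    cov = np.full((l, l), 0.1)
    cov[np.ix_(left, left)] = 0.3
    cov[np.ix_(~left, ~left)] = 0.3
    cov[homotopic] = 0.6
    np.fill_diagonal(cov, 1.0)
    cov = _nearest_unit_diagonal_pd(cov)
    return base, cov


def _scaled_for_class_b(
    base: np.ndarray, cov: np.ndarray, params: SimulationParams
) -> tuple[np.ndarray, np.ndarray]:
    _, inter, _ = _hemisphere_masks(params)
    base_b = base.copy()
    base_b[inter] *= 1.0 - params.delta_s
    cov_b = cov.copy()
    cov_b[inter] *= 1.0 - params.delta_f
    lam = np.linalg.eigvalsh((cov_b + cov_b.T) / 2.0)[0]
    if lam < 1e-6:
        warnings.warn(
            "class-B covariance lost positive definiteness after scaling; "
            "re-loading the diagonal",
            stacklevel=2,
        )
        cov_b = _nearest_unit_diagonal_pd(cov_b)
    return base_b, cov_b


def _structural_subject(
    base: np.ndarray, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative mean-one log-normal edge noise, then integer rounding."""
    l = base.shape[0]
    iu = np.triu_indices(l, k=1)
    s = params.structural_noise
    noise = rng.lognormal(-0.5 * s * s, s, size=len(iu[0])) if s > 0 else 1.0
    w = np.zeros((l, l))
    w[iu] = np.round(base[iu] * noise)
    return w + w.T


def sample_correlation(
    cov: np.ndarray, timepoints: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample Pearson correlation matrix of ``timepoints`` Gaussian draws.

    Finite-sample correlation noise has the geometry of real resting-state
    estimates, unlike additive perturbation of a correlation matrix.
    """
    chol = np.linalg.cholesky(cov)
    ts = rng.standard_normal((timepoints, cov.shape[0])) @ chol.T
    return np.clip(np.corrcoef(ts.T), -1.0, 1.0)


def simulate_dataset(
    params: SimulationParams,
) -> tuple[LabeledGraphDataset, LabeledGraphDataset]:
    """Draw one full synthetic study: (structural, functional) datasets.

    Class A subjects are noisy realizations of the base templates; class B
    subjects are drawn after scaling the inter-hemispheric structural weights
    by ``1 - delta_s`` and inter-hemispheric covariance entries by
    ``1 - delta_f``.  Functional correlation matrices are thresholded at 0
    (positive correlations kept), as in the emulated analysis.
    """
    rng = np.random.default_rng(params.seed)
    labels = node_labels(params)
    base_a, cov_a = make_base_connectomes(params)
    base_b, cov_b = _scaled_for_class_b(base_a, cov_a, params)

    s_graphs, s_labels = [], []
    for cls, base in ((CLASS_A, base_a), (CLASS_B, base_b)):
        for i in range(params.n_per_class_structural):
            w = _structural_subject(base, params, rng)
            s_graphs.append(
                BrainGraph.from_matrix(
                    labels, w, Modality.STRUCTURAL, f"{cls}_s{i + 1:02d}"
                )
            )
            s_labels.append(cls)

    f_graphs, f_labels = [], []
    for cls, cov in ((CLASS_A, cov_a), (CLASS_B, cov_b)):
        for i in range(params.n_per_class_functional):
            corr = sample_correlation(cov, params.functional_timepoints, rng)
            g = BrainGraph.from_matrix(
                labels, np.where(np.eye(params.l, dtype=bool), 0.0, corr),
                Modality.FUNCTIONAL, f"{cls}_f{i + 1:02d}",
            )
            f_graphs.append(threshold_positive(g))
            f_labels.append(cls)

    return (
        LabeledGraphDataset(tuple(s_graphs), tuple(s_labels), labels),
        LabeledGraphDataset(tuple(f_graphs), tuple(f_labels), labels),
    )


@dataclass(frozen=True)
class StudyReport:
    """Replicated-study calibration/power report."""

    per_replicate: pd.DataFrame
    rejection_rate_structural: float
    rejection_rate_functional: float
    rejection_rate_differential: float
    mean_mmd2_structural: float
    mean_mmd2_functional: float
    mean_mmd2_sf: float
    sign_recovery_rate: float
    alpha: float
    replicates: int


def replicate_study(
    params: SimulationParams,
    replicates: int,
    alpha: float = 0.05,
    T: int = 1000,
) -> StudyReport:
    """Re-run the full analysis on many independent simulated studies.

    Each replicate simulates a fresh study (its own seed derived from
    ``params.seed``), runs the kernel two-sample test per modality and the
    differential test, and records statistics and p-values.  The report
    aggregates rejection rates at ``alpha`` and how often the sign of the
    observed differential statistic matches ``sign(delta_s - delta_f)``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    child_seeds = np.random.SeedSequence(params.seed).generate_state(
        3 * replicates
    ) % (2**31)
    rows = []
    truth = np.sign(params.delta_s - params.delta_f)
    for i in range(replicates):
        p_i = replace(params, seed=int(child_seeds[3 * i]))
        ds, df = simulate_dataset(p_i)
        res_s = ktst_test(ds, T=T, seed=int(child_seeds[3 * i + 1]))
        res_f = ktst_test(df, T=T, seed=int(child_seeds[3 * i + 1]))
        res_sf = mmd_sf_test(ds, df, T=T, seed=int(child_seeds[3 * i + 2]))
        rows.append(
            {
                "replicate": i,
                "mmd2_structural": res_s.statistic,
                "p_structural": res_s.p_value,
                "mmd2_functional": res_f.statistic,
                "p_functional": res_f.p_value,
                "mmd2_s": res_sf.mmd2_s,
                "mmd2_f": res_sf.mmd2_f,
                "mmd2_sf": res_sf.mmd2_sf,
                "p_differential": res_sf.p_value,
                "sign_correct": (
                    np.sign(res_sf.mmd2_sf) == truth if truth != 0 else np.nan
                ),
            }
        )
    frame = pd.DataFrame(rows)
    return StudyReport(
        per_replicate=frame,
        rejection_rate_structural=float((frame["p_structural"] <= alpha).mean()),
        rejection_rate_functional=float((frame["p_functional"] <= alpha).mean()),
        rejection_rate_differential=float(
            (frame["p_differential"] <= alpha).mean()
        ),
        mean_mmd2_structural=float(frame["mmd2_structural"].mean()),
        mean_mmd2_functional=float(frame["mmd2_functional"].mean()),
        mean_mmd2_sf=float(frame["mmd2_sf"].mean()),
        sign_recovery_rate=float(frame["sign_correct"].mean())
        if truth != 0
        else float("nan"),
        alpha=alpha,
        replicates=replicates,
    )
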