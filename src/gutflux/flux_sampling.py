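"""Uniform sampling of the feasible flux polytope and flux correlations.

The sampler is artificial-centering hit-and-run (ACHR): warmup points are
optimal vertices of randomized-objective LPs; each chain step picks a
direction from a stored point towards the running center, projects it onto
the null space of S (so mass balance is preserved exactly), finds the
feasible chord within the flux bounds, and jumps to a uniform point on it.
One integer seed determines warmup and chain; the same seed reproduces the
sample matrix bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import null_space

from .constraint_analysis import (
    InfeasibleModelError,
    REPORT_TOL,
    _solve_lp,
    _status_name,
    solve_fba,
)
from .model_io import MetabolicModel, stoichiometric_matrix

__all__ = [
    "FluxSamples",
    "FluxCorrelation",
    "sample_fluxes",
    "flux_correlations",
    "sampling_report",
]

DEFAULT_THINNING = 100
_DIRECTION_TOL = 1e-12
# chord slack: keeps projection dust on bound-tight fixed coordinates from
# pinning every chord at zero length; bound excursions stay ≤ this value and
# do not accumulate (the direction itself is never modified, so mass balance
# is preserved exactly)
_CHORD_SLACK = 1e-7


@dataclass
class FluxSamples:
    """n_samples × n_reactions matrix of feasible flux vectors plus the
    chain metadata needed to reproduce it."""

    matrix: np.ndarray
    reaction_ids: list[str]
    seed: int
    thinning: int
    n_warmup: int

    def column(self, rid: str) -> np.ndarray:
        try:
            j = self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"reaction {rid!r} not in samples") from None
        return self.matrix[:, j]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, columns=self.reaction_ids)


@dataclass
class FluxCorrelation:
    reaction_a: str
    reaction_b: str
    correlation: float | None  # None when either flux is constant
    n_samples: int

    @property
    def defined(self) -> bool:
        return self.correlation is not None


def sample_fluxes(
    model: MetabolicModel,
    n_samples: int,
    seed: int,
    thinning: int = DEFAULT_THINNING,
    n_warmup: int | None = None,
    at_optimum_fraction: float | None = None,
) -> FluxSamples:
    """Draw ``n_samples`` near-uniform flux vectors from {v : S·v = 0,
    lb ≤ v ≤ ub} by ACHR.

    ``at_optimum_fraction`` optionally adds the constraint cᵀv ≥ fraction ·
    optimum (the default samples the whole solution space, not just the
    optimal face).  Warmup uses ``n_warmup`` randomized-objective LP vertices
    (default 2 × n_reactions).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    base = solve_fba(model)
    if not base.optimal:
        raise InfeasibleModelError(
            f"cannot sample: model {model.id!r} is {base.status}"
        )

    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    n = len(model.reactions)
    A_ub = b_ub = None
    if at_optimum_fraction is not None:
        c = np.array([r.objective_coefficient for r in model.reactions])
        floor = at_optimum_fraction * base.objective_value
        A_ub = -c.reshape(1, -1)
        b_ub = np.array([-floor + 1e-9 * max(1.0, abs(floor))])
        S_for_null = S
    else:
        S_for_null = S

    rng = np.random.default_rng(seed)
    if n_warmup is None:
        n_warmup = 2 * n
    n_warmup = max(n_warmup, 4)

    warmup = np.empty((n_warmup, n))
    for k in range(n_warmup):
        c_rand = rng.standard_normal(n)
        res = _solve_lp(c_rand, S, lb, ub, A_ub, b_ub)
        if _status_name(res) != "optimal":
            raise InfeasibleModelError("warmup LP failed; polytope may be empty")
        warmup[k] = res.x

    N = null_space(S_for_null)  # directions live here: S·(N y) = 0 exactly
    if N.size == 0:
        # fully determined fluxes: the polytope is a single point
        matrix = np.repeat(warmup[:1], n_samples, axis=0)
        return FluxSamples(matrix=matrix, reaction_ids=[r.id for r in model.reactions],
                           seed=seed, thinning=thinning, n_warmup=n_warmup)

    center = warmup.mean(axis=0)
    # start at the center: vertices have zero-length chords along pooled
    # directions, the centroid is interior to every non-degenerate facet
    x = center.copy()
    samples = np.empty((n_samples, n))
    stored = warmup.copy()  # direction pool grows with accepted samples
    n_stored = n_warmup
    total_points = n_warmup

    obj_c = None
    obj_floor = None
    if at_optimum_fraction is not None:
        obj_c = np.array([r.objective_coefficient for r in model.reactions])
        obj_floor = at_optimum_fraction * base.objective_value - 1e-9

    collected = 0
    step = 0
    stalls = 0
    while collected < n_samples:
        pick = stored[rng.integers(n_stored)]
        d = pick - center
        d = N @ (N.T @ d)  # exact mass-balance projection
        norm = float(np.linalg.norm(d))
        if norm < _DIRECTION_TOL:
            d = N @ rng.standard_normal(N.shape[1])
            norm = float(np.linalg.norm(d))
            if norm < _DIRECTION_TOL:
                raise RuntimeError("degenerate sampling direction")
        d /= norm

        # feasible chord [amin, amax]; x feasible ⇒ amin ≤ 0 ≤ amax.
        # components with |d| ≤ tol (projection dust on fixed fluxes) are
        # excluded from the ratio tests entirely
        pos = d > _DIRECTION_TOL
        neg = d < -_DIRECTION_TOL
        with np.errstate(divide="ignore", invalid="ignore"):
            to_hi = (ub + _CHORD_SLACK - x) / d
            to_lo = (lb - _CHORD_SLACK - x) / d
        upper = np.minimum(np.where(pos, to_hi, np.inf),
                           np.where(neg, to_lo, np.inf))
        lower = np.maximum(np.where(pos, to_lo, -np.inf),
                           np.where(neg, to_hi, -np.inf))
        amax = float(np.min(upper))
        amin = float(np.max(lower))
        if obj_c is not None:
            cd = float(obj_c @ d)
            cx = float(obj_c @ x)
            if abs(cd) > _DIRECTION_TOL:
                bound = (obj_floor - cx) / cd
                if cd > 0:
                    amin = max(amin, bound)
                else:
                    amax = min(amax, bound)
        if not (math.isfinite(amin) and math.isfinite(amax)) or amax <= amin:
            step += 1
            stalls += 1
            if stalls >= 50:  # trapped on a face: pull back toward the center
                x = 0.5 * (x + center)
                stalls = 0
            continue
        stalls = 0
        alpha = float(rng.uniform(amin, amax))
        x = x + alpha * d  # no clipping: it would break S·v = 0 exactness
        total_points += 1
        center = center + (x - center) / total_points
        step += 1
        if step % thinning == 0:
            samples[collected] = x
            collected += 1
            if n_stored < stored.shape[0]:
                stored[n_stored] = x
                n_stored += 1
            elif rng.random() < 0.1:  # refresh direction pool occasionally
                stored[rng.integers(n_stored)] = x

    # guard: every row mass-balanced and inside bounds at reporting tolerance
    resid = np.abs(S @ samples.T).max() if samples.size else 0.0
    if resid > REPORT_TOL:
        raise RuntimeError(f"sampler drift: max |S·v| = {resid:.2e}")
    return FluxSamples(matrix=samples, reaction_ids=[r.id for r in model.reactions],
                       seed=seed, thinning=thinning, n_warmup=n_warmup)


def flux_correlations(
    samples: FluxSamples, pairs: list[tuple[str, str]]
) -> list[FluxCorrelation]:
    """Pearson correlation per reaction pair; constant fluxes give an
    undefined correlation (``correlation=None``) rather than NaN noise."""
    out = []
    for a, b in pairs:
        va, vb = samples.column(a), samples.column(b)
        sa, sb = float(np.std(va)), float(np.std(vb))
        if sa < 1e-12 or sb < 1e-12:
            corr = None
        else:
            corr = float(np.corrcoef(va, vb)[0, 1])
            corr = max(-1.0, min(1.0, corr))
        out.append(FluxCorrelation(reaction_a=a, reaction_b=b,
                                   correlation=corr, n_samples=samples.n_samples))
    return out


def sampling_report(
    samples: FluxSamples, reactions: list[str], out_dir: str | Path
) -> dict:
    """Histograms, a pairwise scatter matrix and a correlation table for the
    chosen reactions, written under ``out_dir``.  Returns the file manifest.
    """
    import warnings

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"histograms": [], "scatter": None, "correlations": None}
    if not reactions:
        warnings.warn("sampling_report: empty reaction list, nothing to plot")
        return manifest
    for rid in reactions:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(samples.column(rid), bins=40, color="steelblue")
        ax.set_xlabel(f"{rid} flux (mmol/gDW/h)")
        ax.set_ylabel("count")
        fig.tight_layout()
        p = out_dir / f"hist_{rid}.png"
        fig.savefig(p)
        plt.close(fig)
        manifest["histograms"].append(str(p))

    k = len(reactions)
    fig, axes = plt.subplots(k, k, figsize=(2.2 * k, 2.2 * k), squeeze=False)
    for i, ri in enumerate(reactions):
        for j, rj in enumerate(reactions):
            ax = axes[i][j]
            if i == j:
                ax.hist(samples.column(ri), bins=30, color="grey")
            else:
                ax.plot(samples.column(rj), samples.column(ri), ".",
                        markersize=1, alpha=0.4)
            if i == k - 1:
                ax.set_xlabel(rj, fontsize=7)
            if j == 0:
                ax.set_ylabel(ri, fontsize=7)
            ax.tick_params(labelsize=6)
    fig.tight_layout()
    p = out_dir / "scatter_matrix.png"
    fig.savefig(p)
    plt.close(fig)
    manifest["scatter"] = str(p)

    pairs = [(a, b) for a in reactions for b in reactions]
    corrs = flux_correlations(samples, pairs)
    table = pd.DataFrame(
        np.array([c.correlation if c.defined else np.nan for c in corrs]).reshape(k, k),
        index=reactions, columns=reactions,
    )
    p = out_dir / "correlations.tsv"
    table.to_csv(p, sep="\t")
    manifest["correlations"] = str(p)
    return manifest
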