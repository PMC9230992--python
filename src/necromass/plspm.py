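"""Partial least squares path modeling (PLS-PM).

Estimates a directed acyclic network of latent variables, each measured by
a block of observed indicators (reflective, Mode A), by the classical
alternating outer/inner approximation: latent scores are weighted sums of
standardized indicators, inner proxies combine neighbouring latents (path
weighting scheme by default), and outer weights are updated as
indicator-proxy correlations until convergence.  Path coefficients are OLS
regressions of each endogenous latent on its predecessors; model quality
is summarised by per-latent R-squared, per-block communality (mean squared
loading) and the goodness-of-fit index GoF = sqrt(mean communality x mean
R-squared), with GoF > 0.7 conventionally read as acceptable overall
prediction performance.  Effects decompose as total = direct + indirect,
the indirect part summing products of coefficients over all directed paths
of length >= 2.  Significance comes from a nonparametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


class ConvergenceError(RuntimeError):
    """Raised when the outer-weight iteration fails to converge."""


@dataclass(frozen=True)
class PathModelSpec:
    """Latent blocks and inner structure of a PLS path model.

    ``blocks`` maps each latent-variable name to its indicator columns;
    ``paths`` lists directed (source, target) latent pairs and must form a
    DAG.  Estimation is reflective (Mode A) with the ``path`` inner
    weighting scheme by default (``centroid`` and ``factor`` available).
    """

    blocks: dict[str, list[str]]
    paths: list[tuple[str, str]]
    scheme: str = "path"
    tolerance: float = 1e-7
    max_iterations: int = 300

    def __post_init__(self) -> None:
        if self.scheme not in ("path", "centroid", "factor"):
            raise ValueError(f"unknown inner scheme {self.scheme!r}")
        seen: dict[str, str] = {}
        for latent, cols in self.blocks.items():
            if not cols:
                raise ValueError(f"block {latent!r} is empty")
            for c in cols:
                if c in seen:
                    raise ValueError(
                        f"indicator {c!r} appears in blocks {seen[c]!r} and {latent!r}"
                    )
                seen[c] = latent
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("inner path structure must be acyclic")
        for s, t in self.paths:
            if s not in self.blocks or t not in self.blocks:
                raise ValueError(f"path ({s!r}, {t!r}) references an unknown latent")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.blocks)
        g.add_edges_from(self.paths)
        return g

    @property
    def latents(self) -> list[str]:
        return list(self.blocks)

    @property
    def endogenous(self) -> list[str]:
        targets = {t for _, t in self.paths}
        return [l for l in self.latents if l in targets]


@dataclass
class PlsPmResult:
    """Fitted PLS path model."""

    spec: PathModelSpec
    scores: pd.DataFrame  # samples x latents, unit variance
    outer_weights: dict[str, pd.Series]
    loadings: dict[str, pd.Series]
    path_coefficients: pd.DataFrame  # source x target matrix (0 where no edge)
    r2: dict[str, float]
    communality: dict[str, float]
    gof: float
    n_iterations: int

    @property
    def gof_acceptable(self) -> bool:
        return self.gof > 0.7


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance indicator")
    return (x - x.mean(axis=0)) / sd


def fit_plspm(data: pd.DataFrame, spec: PathModelSpec) -> PlsPmResult:
    """Fit a PLS path model by the alternating outer/inner algorithm.

    Indicators are standardized (ddof=1); latent scores are kept at unit
    variance throughout.  Iteration stops when the summed squared change
    of absolute outer weights falls below ``spec.tolerance``.  Each latent's
    orientation is fixed so its dominant loading is positive.  With
    single-indicator blocks the model reduces exactly to standardized OLS
    path analysis.
    """
    latents = spec.latents
    n = len(data)
    if n < len(latents) + 2:
        raise ValueError("too few samples for the number of latent variables")
    cols = [c for l in latents for c in spec.blocks[l]]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data missing indicator columns: {missing}")
    if data[cols].isna().any().any():
        raise ValueError("missing values in indicator columns")

    x_blocks = {l: _standardize(data[spec.blocks[l]].to_numpy(float)) for l in latents}
    weights = {l: np.ones(len(spec.blocks[l])) for l in latents}
    graph = spec.graph()
    neighbors = {
        l: sorted(set(graph.predecessors(l)) | set(graph.successors(l))) for l in latents
    }

    def scores_from(w: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for l in latents:
            y = x_blocks[l] @ w[l]
            out[l] = y / y.std(ddof=1)
        return out

    y = scores_from(weights)
    n_iter = 0
    for n_iter in range(1, spec.max_iterations + 1):
        # inner approximation
        z: dict[str, np.ndarray] = {}
        for l in latents:
            nb = neighbors[l]
            if not nb:
                z[l] = y[l]
                continue
            if spec.scheme == "centroid":
                e = {m: np.sign(np.corrcoef(y[l], y[m])[0, 1]) for m in nb}
            elif spec.scheme == "factor":
                e = {m: np.corrcoef(y[l], y[m])[0, 1] for m in nb}
            else:  # path scheme
                e = {}
                preds = sorted(graph.predecessors(l))
                if preds:
                    xp = np.column_stack([y[m] for m in preds])
                    beta, *_ = np.linalg.lstsq(xp, y[l], rcond=None)
                    for m, b in zip(preds, beta):
                        e[m] = b
                for m in graph.successors(l):
                    e[m] = np.corrcoef(y[l], y[m])[0, 1]
            zl = sum(e[m] * y[m] for m in nb)
            sd = zl.std(ddof=1)
            z[l] = zl / sd if sd > 0 else y[l]
        # outer approximation, Mode A
        new_weights = {}
        for l in latents:
            w = x_blocks[l].T @ z[l] / (n - 1)  # corr(x, z): both standardized
            yl = x_blocks[l] @ w
            sd = yl.std(ddof=1)
            if sd == 0:
                raise ConvergenceError(f"degenerate latent {l!r} (zero-variance score)")
            new_weights[l] = w / sd
        # sign indeterminacy: orient each block so its dominant weight is
        # positive, preventing flip-flop between iterations
        for l in latents:
            w = new_weights[l]
            if w[np.argmax(np.abs(w))] < 0:
                new_weights[l] = -w
        # convergence on the summed squared change of |weights|, the
        # stopping rule of classical PLS-PM implementations
        delta = sum(
            float(np.sum((np.abs(new_weights[l]) - np.abs(weights[l])) ** 2))
            for l in latents
        )
        weights = new_weights
        y = scores_from(weights)
        if delta < spec.tolerance:
            break
    else:
        raise ConvergenceError(
            f"PLS-PM did not converge in {spec.max_iterations} iterations"
        )

    # orientation: dominant loading positive
    for l in latents:
        load = x_blocks[l].T @ y[l] / (n - 1)
        if load[np.argmax(np.abs(load))] < 0:
            weights[l] = -weights[l]
            y[l] = -y[l]

    scores = pd.DataFrame({l: y[l] for l in latents}, index=data.index)
    loadings = {
        l: pd.Series(x_blocks[l].T @ y[l] / (n - 1), index=spec.blocks[l])
        for l in latents
    }
    communality = {l: float((loadings[l] ** 2).mean()) for l in latents}

    paths_mat = pd.DataFrame(0.0, index=latents, columns=latents)
    r2: dict[str, float] = {}
    for l in spec.endogenous:
        preds = sorted(graph.predecessors(l))
        xp = np.column_stack([y[m] for m in preds])
        beta, *_ = np.linalg.lstsq(xp, y[l], rcond=None)
        fitted = xp @ beta
        r2[l] = float(np.var(fitted, ddof=1))  # y[l] has unit variance
        for m, b in zip(preds, beta):
            paths_mat.loc[m, l] = float(b)

    mean_comm = float(np.mean([communality[l] for l in latents]))
    mean_r2 = float(np.mean(list(r2.values()))) if r2 else np.nan
    gof = float(np.sqrt(mean_comm * mean_r2)) if r2 else np.nan
    return PlsPmResult(
        spec=spec,
        scores=scores,
        outer_weights={l: pd.Series(weights[l], index=spec.blocks[l]) for l in latents},
        loadings=loadings,
        path_coefficients=paths_mat,
        r2=r2,
        communality=communality,
        gof=gof,
        n_iterations=n_iter,
    )


def goodness_of_fit(result: PlsPmResult) -> float:
    """GoF = sqrt(mean block communality x mean endogenous R-squared)."""
    if not result.r2:
        raise ValueError("model has no endogenous latent variable")
    mean_comm = float(np.mean(list(result.communality.values())))
    mean_r2 = float(np.mean(list(result.r2.values())))
    return float(np.sqrt(mean_comm * mean_r2))


def effects_from_matrix(paths: pd.DataFrame) -> pd.DataFrame:
    """Direct/indirect/total standardized effects from a path matrix.

    The inner structure is acyclic, so the matrix power series
    sum_{k>=1} B^k is finite; indirect = total - direct.  Returns one row
    per ordered latent pair with a nonzero total effect or a direct edge.
    """
    latents = list(paths.index)
    b = paths.to_numpy(float)
    total = np.zeros_like(b)
    power = b.copy()
    for _ in range(len(latents)):
        total += power
        power = power @ b
        if not power.any():
            break
    rows = []
    for i, s in enumerate(latents):
        for j, t in enumerate(latents):
            if b[i, j] != 0 or abs(total[i, j]) > 1e-15:
                rows.append(
                    {
                        "source": s,
                        "target": t,
                        "direct": b[i, j],
                        "indirect": total[i, j] - b[i, j],
                        "total": total[i, j],
                    }
                )
    return pd.DataFrame(rows, columns=["source", "target", "direct", "indirect", "total"])


def total_effects(result: PlsPmResult) -> pd.DataFrame:
    """Standardized direct, indirect and total effects of the fitted model."""
    return effects_from_matrix(result.path_coefficients)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class BootstrapResult:
    """Bootstrap distribution summary for path coefficients and total effects."""

    paths: pd.DataFrame  # per inner edge: original, boot mean, se, CI, p, stars
    total: pd.DataFrame
    n_boot: int
    n_failed: int


def bootstrap_plspm(
    data: pd.DataFrame,
    spec: PathModelSpec,
    n_boot: int = 500,
    seed: int = 0,
    ci: float = 0.95,
) -> BootstrapResult:
    """Bootstrap significance for path coefficients and total effects.

    Samples are resampled with replacement and the model refitted; each
    replicate's latent orientations are sign-aligned to the full-sample fit
    via the outer weights.  Reports percentile confidence intervals and a
    two-sided sign-based p with star categories (* <0.05, ** <0.01,
    *** <0.001).  Aborts if more than 5% of replicates fail to refit.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    full = fit_plspm(data, spec)
    edges = spec.paths
    eff_full = total_effects(full).set_index(["source", "target"])
    rng = np.random.default_rng(seed)
    n = len(data)
    path_draws = {e: [] for e in edges}
    total_draws = {e: [] for e in eff_full.index}
    n_failed = 0
    max_failed = int(0.05 * n_boot)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            fit = fit_plspm(data.iloc[idx].reset_index(drop=True), spec)
        except (ConvergenceError, ValueError):
            n_failed += 1
            if n_failed > max_failed:
                raise ConvergenceError(
                    f"{n_failed} bootstrap replicates failed (> 5% of {n_boot})"
                )
            continue
        flip = {
            l: -1.0
            if float(fit.outer_weights[l] @ full.outer_weights[l]) < 0
            else 1.0
            for l in spec.latents
        }
        pm = fit.path_coefficients.copy()
        for l, f in flip.items():
            if f < 0:
                pm.loc[l, :] *= -1
                pm.loc[:, l] *= -1
        for e in edges:
            path_draws[e].append(float(pm.loc[e[0], e[1]]))
        eff = effects_from_matrix(pm).set_index(["source", "target"])
        for e in total_draws:
            total_draws[e].append(float(eff["total"].get(e, 0.0)))

    lo, hi = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2

    def summarize(draws: dict, originals: dict) -> pd.DataFrame:
        rows = []
        for e, vals in draws.items():
            v = np.asarray(vals)
            n_eff = len(v)
            p = 2 * min((v <= 0).sum() + 1, (v >= 0).sum() + 1) / (n_eff + 1)
            p = min(p, 1.0)
            rows.append(
                {
                    "source": e[0],
                    "target": e[1],
                    "original": originals[e],
                    "boot_mean": v.mean(),
                    "se": v.std(ddof=1),
                    "ci_low": np.percentile(v, lo),
                    "ci_high": np.percentile(v, hi),
                    "p": p,
                    "stars": _stars(p),
                }
            )
        return pd.DataFrame(rows)

    path_orig = {e: float(full.path_coefficients.loc[e[0], e[1]]) for e in edges}
    tot_orig = {e: float(eff_full["total"].get(e, 0.0)) for e in total_draws}
    return BootstrapResult(
        paths=summarize(path_draws, path_orig),
        total=summarize(total_draws, tot_orig),
        n_boot=n_boot,
        n_failed=n_failed,
    )
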