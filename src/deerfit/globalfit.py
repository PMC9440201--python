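"""Global Gaussian-mixture analysis of DEER decays.

Several decays recorded on the same spin-labeled pair under different
conditions (pH, micelle vs nanodisc) are fitted jointly: the conformers'
Gaussian centers and widths are shared across conditions, the conformer
populations are free per condition, and the intermolecular background and
modulation depth are free per trace. The number of components is chosen by
an information criterion (BIC by default, AICc optional), and pointwise 2σ
confidence bands on P(r) follow from first-order (delta-method) propagation
of the parameter covariance.

Population fractions are parameterized through a softmax over per-condition
logits (last logit pinned at zero), which enforces Σ_k a_ck = 1 exactly
while keeping the optimization unconstrained and the population
uncertainties differentiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .distributions import (
    DistanceDistribution,
    DistanceGrid,
    GaussianComponent,
)
from .forward import DipolarTrace, dipolar_kernel

__all__ = [
    "ConditionSet",
    "GlobalFitResult",
    "GlobalGaussianFitter",
    "FitError",
    "fit_single",
    "fit_global",
    "choose_model",
    "confidence_band",
    "bootstrap_band",
    "state_population",
]

_SIGMA_BOUNDS = (0.05, 1.5)
_DELTA_BOUNDS = (0.02, 0.8)
_DIM_BOUNDS = (2.0, 3.5)
_LOGIT_BOUND = 12.0
_KAPPA_MAX = 20.0


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best attempt if any."""

    def __init__(self, message: str, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


@dataclass
class ConditionSet:
    """DEER decays of one spin pair under several conditions.

    Traces sharing a label belong to the same condition (same conformer
    populations); each trace keeps its own background and modulation depth.
    """

    traces: list[DipolarTrace]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.traces) < 1:
            raise ValueError("need at least one trace")
        if self.labels is None:
            self.labels = [
                t.meta.get("label", f"condition-{i}")
                for i, t in enumerate(self.traces)
            ]
        if len(self.labels) != len(self.traces):
            raise ValueError("labels and traces have mismatched lengths")
        pairs = {t.pair for t in self.traces if t.pair is not None}
        if len(pairs) > 1:
            raise ValueError(
                f"all traces must come from the same spin pair, got {sorted(pairs)}"
            )

    @property
    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    @property
    def condition_index(self) -> np.ndarray:
        order = self.condition_labels
        return np.array([order.index(lab) for lab in self.labels])


class _Layout:
    """Index bookkeeping for the packed parameter vector."""

    def __init__(self, K: int, n_cond: int, n_traces: int, vary_dim: bool):
        self.K = K
        self.n_cond = n_cond
        self.n_traces = n_traces
        self.vary_dim = vary_dim
        self.centers = slice(0, K)
        self.widths = slice(K, 2 * K)
        n = 2 * K
        self.logits = []
        for _ in range(n_cond):
            self.logits.append(slice(n, n + K - 1))
            n += K - 1
        self.per_trace = 3 if vary_dim else 2
        self.trace_block = slice(n, n + n_traces * self.per_trace)
        self.n_params = n + n_traces * self.per_trace

    def delta(self, t: int) -> int:
        return self.trace_block.start + t * self.per_trace

    def kappa(self, t: int) -> int:
        return self.trace_block.start + t * self.per_trace + 1

    def dim(self, t: int) -> int:
        return self.trace_block.start + t * self.per_trace + 2


def _softmax_populations(logits: np.ndarray) -> np.ndarray:
    full = np.append(logits, 0.0)
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def _component_basis(r: np.ndarray, centers, widths, step):
    """Per-component densities normalized to unit trapezoid integral, plus
    their derivatives w.r.t. center and width."""
    K = len(centers)
    phi = np.empty((K, r.size))
    dphi_dr0 = np.empty_like(phi)
    dphi_ds = np.empty_like(phi)
    wr = np.full(r.size, step)
    wr[0] = wr[-1] = 0.5 * step
    for k in range(K):
        x = (r - centers[k]) / widths[k]
        g = np.exp(-0.5 * x * x)
        z = float(wr @ g)
        dg_dr0 = g * x / widths[k]
        dg_ds = g * x * x / widths[k]
        dz_dr0 = float(wr @ dg_dr0)
        dz_ds = float(wr @ dg_ds)
        phi[k] = g / z
        dphi_dr0[k] = (dg_dr0 - phi[k] * dz_dr0) / z
        dphi_ds[k] = (dg_ds - phi[k] * dz_ds) / z
    return phi, dphi_dr0, dphi_ds


@dataclass
class GlobalFitResult:
    """Converged global fit: shared shapes, per-condition populations,
    per-trace nuisance parameters, covariance, and criterion table."""

    n_components: int
    grid: DistanceGrid
    condition_labels: list[str]
    centers: np.ndarray  # (K,), sorted ascending
    widths: np.ndarray  # (K,)
    populations: np.ndarray  # (n_cond, K), rows sum to 1
    depths: np.ndarray  # (n_traces,)
    kappas: np.ndarray  # (n_traces,)
    dims: np.ndarray  # (n_traces,)
    rss: np.ndarray  # per-trace residual sum of squares
    n_points: np.ndarray  # per-trace point counts
    noise_sigmas: np.ndarray  # per-trace noise std estimated from residuals
    objective: float
    criterion: str
    criterion_values: dict[int, float] = field(default_factory=dict)
    objectives: dict[int, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    # internals for uncertainty propagation (parameters in fit order)
    _theta: np.ndarray | None = None
    _cov: np.ndarray | None = None
    _layout: _Layout | None = None
    _order: np.ndarray | None = None
    _cond_index: np.ndarray | None = None
    _traces: list | None = None

    @property
    def covariance(self) -> np.ndarray | None:
        return self._cov

    def components(self, condition: int | str = 0) -> list[GaussianComponent]:
        c = self._resolve_condition(condition)
        return [
            GaussianComponent(self.centers[k], self.widths[k], self.populations[c, k])
            for k in range(self.n_components)
        ]

    def distribution(self, condition: int | str = 0) -> DistanceDistribution:
        return DistanceDistribution.from_components(
            self.components(condition), self.grid
        )

    def _resolve_condition(self, condition: int | str) -> int:
        if isinstance(condition, str):
            return self.condition_labels.index(condition)
        return int(condition)

    def confidence_band(self, condition: int | str = 0, level: float = 2.0):
        return confidence_band(self, level=level, condition=condition)

    def state_population(self, selector, condition: int | str = 0):
        return state_population(self, selector, condition)

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "condition_labels": list(self.condition_labels),
            "centers_nm": self.centers.tolist(),
            "widths_nm": self.widths.tolist(),
            "populations": self.populations.tolist(),
            "modulation_depths": self.depths.tolist(),
            "background_kappa": self.kappas.tolist(),
            "background_dim": self.dims.tolist(),
            "rss": self.rss.tolist(),
            "noise_sigmas": self.noise_sigmas.tolist(),
            "objective": self.objective,
            "criterion": self.criterion,
            "criterion_values": {str(k): v for k, v in self.criterion_values.items()},
            "warnings": list(self.warnings),
        }


class GlobalGaussianFitter(BaseEstimator):
    """Fit a shared sum-of-Gaussians P(r) to one or more DEER decays.

    Parameters
    ----------
    n_components : int
        Number of Gaussian conformer components K.
    grid : DistanceGrid, optional
        Distance axis for P(r); defaults to 1.5–8 nm, 0.02 nm step.
    n_restarts : int
        Multi-start attempts; centers are seeded evenly over the grid
        interior and jittered by a seeded generator on later restarts.
    vary_background_dim : bool
        If True the stretched-exponential exponent d is fitted per trace
        within [2, 3.5]; by default it stays at `background_dim` (3 =
        homogeneous 3-D bath), which avoids the near-degeneracy between
        kappa and d on short traces.
    criterion : {"bic", "aicc"}
        Information criterion recorded per candidate model size.
    include_background_uncertainty : bool
        If True (default), confidence bands use the full parameter
        covariance, so correlations with the background/depth parameters
        widen the band; if False the shape-parameter block is inverted
        alone (backgrounds treated as known).
    random_state : int
        Seed for restart jitter.

    Attributes (after fit)
    ----------------------
    centers_, widths_ : (K,) arrays, sorted by center.
    populations_ : (n_conditions, K) array, rows sum to 1.
    depths_, kappas_, dims_ : per-trace nuisance parameters.
    result_ : GlobalFitResult with covariance and criterion table.
    """

    def __init__(
        self,
        n_components: int = 2,
        grid: DistanceGrid | None = None,
        n_restarts: int = 8,
        vary_background_dim: bool = False,
        background_dim: float = 3.0,
        criterion: str = "bic",
        include_background_uncertainty: bool = True,
        random_state: int = 0,
        max_nfev: int = 400,
    ):
        self.n_components = n_components
        self.grid = grid
        self.n_restarts = n_restarts
        self.vary_background_dim = vary_background_dim
        self.background_dim = background_dim
        self.criterion = criterion
        self.include_background_uncertainty = include_background_uncertainty
        self.random_state = random_state
        self.max_nfev = max_nfev

    # ------------------------------------------------------------------ fit

    def fit(self, X, y=None, init: dict | None = None):
        """Fit the global model to `X` (a ConditionSet or list of traces)."""
        conditions = X if isinstance(X, ConditionSet) else ConditionSet(list(X))
        K = int(self.n_components)
        if K < 1:
            raise ValueError("n_components must be >= 1")
        grid = self.grid or DistanceGrid()
        layout = _Layout(
            K,
            len(conditions.condition_labels),
            len(conditions.traces),
            self.vary_background_dim,
        )
        cond_index = conditions.condition_index
        r = grid.values
        wr = np.full(r.size, grid.step)
        wr[0] = wr[-1] = 0.5 * grid.step
        kernels = [dipolar_kernel(tr.t, grid) * wr for tr in conditions.traces]
        data = [tr.V for tr in conditions.traces]
        taus = [tr.t for tr in conditions.traces]

        theta0_list = self._initial_guesses(conditions, grid, layout, init)
        lo, hi = self._bounds(grid, layout)

        best = None
        for theta0 in theta0_list:
            theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)
            try:
                sol = least_squares(
                    self._residuals,
                    theta0,
                    jac=self._jacobian,
                    bounds=(lo, hi),
                    args=(layout, cond_index, r, grid.step, kernels, data, taus),
                    method="trf",
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                    max_nfev=self.max_nfev,
                )
            except Exception:  # singular step, etc. — try next start
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitError("all multi-start attempts failed")

        self.result_ = self._pack_result(
            best, layout, conditions, grid, cond_index, kernels, data, taus
        )
        self.centers_ = self.result_.centers
        self.widths_ = self.result_.widths
        self.populations_ = self.result_.populations
        self.depths_ = self.result_.depths
        self.kappas_ = self.result_.kappas
        self.dims_ = self.result_.dims
        self.objective_ = self.result_.objective
        return self

    # ---------------------------------------------------------- model parts

    @staticmethod
    def _unpack_model(theta, layout, cond_index, r, step, kernels, taus):
        K = layout.K
        centers = theta[layout.centers]
        widths = theta[layout.widths]
        phi, dphi_dr0, dphi_ds = _component_basis(r, centers, widths, step)
        pops = np.empty((layout.n_cond, K))
        for c in range(layout.n_cond):
            if K == 1:
                pops[c] = 1.0
            else:
                pops[c] = _softmax_populations(theta[layout.logits[c]])
        P = pops @ phi  # (n_cond, n_r)
        traces = []
        for t_idx in range(layout.n_traces):
            c = cond_index[t_idx]
            delta = theta[layout.delta(t_idx)]
            kappa = theta[layout.kappa(t_idx)]
            dim = theta[layout.dim(t_idx)] if layout.vary_dim else None
            m = kernels[t_idx] @ P[c]
            traces.append((c, delta, kappa, dim, m))
        return centers, widths, phi, dphi_dr0, dphi_ds, pops, P, traces

    def _residuals(self, theta, layout, cond_index, r, step, kernels, data, taus):
        out = []
        *_, traces = self._unpack_model(
            theta, layout, cond_index, r, step, kernels, taus
        )
        for t_idx, (c, delta, kappa, dim, m) in enumerate(traces):
            d = dim if layout.vary_dim else self.background_dim
            B = np.exp(-kappa * taus[t_idx] ** (d / 3.0))
            V = B * ((1.0 - delta) + delta * m)
            out.append(V - data[t_idx])
        return np.concatenate(out)

    def _jacobian(self, theta, layout, cond_index, r, step, kernels, data, taus):
        K = layout.K
        centers, widths, phi, dphi_dr0, dphi_ds, pops, P, traces = self._unpack_model(
            theta, layout, cond_index, r, step, kernels, taus
        )
        n_rows = sum(len(tau) for tau in taus)
        J = np.zeros((n_rows, layout.n_params))
        row = 0
        for t_idx, (c, delta, kappa, dim, m) in enumerate(traces):
            tau = taus[t_idx]
            n = tau.size
            d = dim if layout.vary_dim else self.background_dim
            td = tau ** (d / 3.0)
            B = np.exp(-kappa * td)
            F = (1.0 - delta) + delta * m
            V = B * F
            Kw = kernels[t_idx]
            a = pops[c]
            # shared shape parameters
            for k in range(K):
                J[row : row + n, layout.centers.start + k] = (
                    B * delta * (Kw @ (a[k] * dphi_dr0[k]))
                )
                J[row : row + n, layout.widths.start + k] = (
                    B * delta * (Kw @ (a[k] * dphi_ds[k]))
                )
            # per-condition population logits
            if K > 1:
                for j in range(K - 1):
                    dP = a[j] * (phi[j] - P[c])
                    J[row : row + n, layout.logits[c].start + j] = (
                        B * delta * (Kw @ dP)
                    )
            # per-trace nuisances
            J[row : row + n, layout.delta(t_idx)] = B * (m - 1.0)
            J[row : row + n, layout.kappa(t_idx)] = -td * V
            if layout.vary_dim:
                with np.errstate(divide="ignore", invalid="ignore"):
                    dtd = np.where(tau > 0, np.log(tau) * td / 3.0, 0.0)
                J[row : row + n, layout.dim(t_idx)] = -kappa * dtd * V
            row += n
        return J

    # ------------------------------------------------------- initialization

    def _initial_guesses(self, conditions, grid, layout, init):
        K = layout.K
        rng = np.random.default_rng(self.random_state)
        lo_r = grid.r_min + 0.1 * (grid.r_max - grid.r_min)
        hi_r = grid.r_max - 0.25 * (grid.r_max - grid.r_min)
        base_centers = np.linspace(lo_r, hi_r, K + 2)[1:-1] if K > 1 else np.array(
            [0.5 * (lo_r + hi_r)]
        )
        guesses = []
        deltas0 = [0.3, 0.45, 0.2, 0.6]
        for i in range(max(1, int(self.n_restarts))):
            theta = np.zeros(layout.n_params)
            if i == 0:
                theta[layout.centers] = base_centers
            else:
                jitter = rng.uniform(-0.4, 0.4, K) * (hi_r - lo_r) / max(K, 2)
                theta[layout.centers] = np.clip(
                    base_centers + jitter, grid.r_min + 0.1, grid.r_max - 0.1
                )
            theta[layout.widths] = 0.3
            for c in range(layout.n_cond):
                theta[layout.logits[c]] = rng.uniform(-0.3, 0.3, K - 1) if i else 0.0
            for t_idx, tr in enumerate(conditions.traces):
                v_end = float(np.clip(tr.V[-1], 0.02, 0.98))
                theta[layout.delta(t_idx)] = deltas0[i % len(deltas0)]
                theta[layout.kappa(t_idx)] = max(
                    0.5 * -np.log(v_end) / max(tr.t[-1], 1e-6), 1e-3
                )
                if layout.vary_dim:
                    theta[layout.dim(t_idx)] = 3.0
            guesses.append(theta)
        if init:
            theta = guesses[0].copy()
            if "centers" in init:
                theta[layout.centers] = np.asarray(init["centers"], float)
            if "widths" in init:
                theta[layout.widths] = np.asarray(init["widths"], float)
            if "populations" in init and K > 1:
                pops = np.atleast_2d(np.asarray(init["populations"], float))
                for c in range(layout.n_cond):
                    p = np.clip(pops[min(c, len(pops) - 1)], 1e-6, 1.0)
                    theta[layout.logits[c]] = np.log(p[:-1] / p[-1])
            if "delta" in init:
                for t_idx in range(layout.n_traces):
                    theta[layout.delta(t_idx)] = float(init["delta"])
            if "kappa" in init:
                for t_idx in range(layout.n_traces):
                    theta[layout.kappa(t_idx)] = float(init["kappa"])
            guesses.insert(0, theta)
        return guesses

    def _bounds(self, grid, layout):
        lo = np.empty(layout.n_params)
        hi = np.empty(layout.n_params)
        lo[layout.centers] = grid.r_min
        hi[layout.centers] = grid.r_max
        lo[layout.widths] = _SIGMA_BOUNDS[0]
        hi[layout.widths] = _SIGMA_BOUNDS[1]
        for c in range(layout.n_cond):
            lo[layout.logits[c]] = -_LOGIT_BOUND
            hi[layout.logits[c]] = _LOGIT_BOUND
        for t_idx in range(layout.n_traces):
            lo[layout.delta(t_idx)] = _DELTA_BOUNDS[0]
            hi[layout.delta(t_idx)] = _DELTA_BOUNDS[1]
            lo[layout.kappa(t_idx)] = 0.0
            hi[layout.kappa(t_idx)] = _KAPPA_MAX
            if layout.vary_dim:
                lo[layout.dim(t_idx)] = _DIM_BOUNDS[0]
                hi[layout.dim(t_idx)] = _DIM_BOUNDS[1]
        return lo, hi

    # ------------------------------------------------------------ reporting

    def _pack_result(
        self, sol, layout, conditions, grid, cond_index, kernels, data, taus
    ):
        K = layout.K
        theta = sol.x
        r = grid.values
        res = self._residuals(
            theta, layout, cond_index, r, grid.step, kernels, data, taus
        )
        n_points = np.array([len(tau) for tau in taus])
        edges = np.concatenate([[0], np.cumsum(n_points)])
        rss = np.array(
            [float(np.sum(res[edges[i] : edges[i + 1]] ** 2)) for i in range(len(taus))]
        )
        p_per_trace = layout.per_trace
        dof = np.maximum(n_points - (2 * K + (K - 1) + p_per_trace), 1)
        noise = np.sqrt(rss / dof)

        centers = theta[layout.centers].copy()
        widths = theta[layout.widths].copy()
        pops = np.empty((layout.n_cond, K))
        for c in range(layout.n_cond):
            pops[c] = (
                _softmax_populations(theta[layout.logits[c]]) if K > 1 else np.array([1.0])
            )
        depths = np.array([theta[layout.delta(t)] for t in range(layout.n_traces)])
        kappas = np.array([theta[layout.kappa(t)] for t in range(layout.n_traces)])
        dims = (
            np.array([theta[layout.dim(t)] for t in range(layout.n_traces)])
            if layout.vary_dim
            else np.full(layout.n_traces, self.background_dim)
        )

        # weighted covariance: rows scaled by 1/sigma_t
        J = self._jacobian(theta, layout, cond_index, r, grid.step, kernels, data, taus)
        w = np.concatenate(
            [np.full(n_points[i], 1.0 / max(noise[i], 1e-10)) for i in range(len(taus))]
        )
        Jw = J * w[:, None]
        JtJ = Jw.T @ Jw
        cov = None
        try:
            cov = np.linalg.pinv(JtJ, rcond=1e-12)
        except np.linalg.LinAlgError:
            cov = None
        # tiny-noise fits: pinv of a huge-scale matrix is fine; cov ~ noise^2

        warn_msgs = []
        if np.any(depths <= _DELTA_BOUNDS[0] + 1e-3):
            msg = (
                "modulation depth at its lower bound: trace is background-"
                "dominated and P(r) is poorly constrained"
            )
            warn_msgs.append(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)

        order = np.argsort(centers)
        result = GlobalFitResult(
            n_components=K,
            grid=grid,
            condition_labels=conditions.condition_labels,
            centers=centers[order],
            widths=widths[order],
            populations=pops[:, order],
            depths=depths,
            kappas=kappas,
            dims=dims,
            rss=rss,
            n_points=n_points,
            noise_sigmas=noise,
            objective=float(np.sum(rss)),
            criterion=self.criterion,
            warnings=warn_msgs,
            _theta=theta,
            _cov=cov,
            _layout=layout,
            _order=order,
            _cond_index=cond_index,
            _traces=list(conditions.traces),
        )
        return result


# ----------------------------------------------------------- criterion table


def _criterion_value(name: str, rss, n_points, n_params: int) -> float:
    """Gaussian-likelihood information criterion on concatenated residuals,
    with the noise variance estimated per trace."""
    n_total = int(np.sum(n_points))
    loglik_term = float(
        np.sum(n_points * np.log(np.maximum(rss / n_points, 1e-300)))
    )
    if name == "bic":
        return loglik_term + n_params * np.log(n_total)
    if name == "aicc":
        corr = (
            2.0 * n_params * (n_params + 1) / max(n_total - n_params - 1, 1)
        )
        return loglik_term + 2.0 * n_params + corr
    raise ValueError(f"unknown criterion {name!r}")


def _n_free_params(layout: _Layout) -> int:
    return layout.n_params


# ------------------------------------------------------- functional wrappers


def fit_single(
    trace: DipolarTrace, K: int, init: dict | None = None, **kwargs
) -> GlobalFitResult:
    """Fit one trace alone (a single-condition global fit)."""
    fitter = GlobalGaussianFitter(n_components=K, **kwargs)
    fitter.fit(ConditionSet([trace]), init=init)
    res = fitter.result_
    res.criterion_values[K] = _criterion_value(
        fitter.criterion, res.rss, res.n_points, _n_free_params(res._layout)
    )
    res.objectives[K] = res.objective
    return res


def fit_global(
    conditions: ConditionSet, K: int, init: dict | None = None, **kwargs
) -> GlobalFitResult:
    """Global fit with shared centers/widths, per-condition populations."""
    fitter = GlobalGaussianFitter(n_components=K, **kwargs)
    fitter.fit(conditions, init=init)
    res = fitter.result_
    res.criterion_values[K] = _criterion_value(
        fitter.criterion, res.rss, res.n_points, _n_free_params(res._layout)
    )
    res.objectives[K] = res.objective
    return res


def choose_model(
    conditions: ConditionSet, K_max: int = 4, **kwargs
) -> GlobalFitResult:
    """Fit K = 1..K_max and return the fit minimizing the criterion.

    Each K > 1 additionally warm-starts from the best (K-1)-component
    solution with a small extra component, which makes the objective
    non-increasing in K. Ties break toward smaller K.
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    results: dict[int, GlobalFitResult] = {}
    errors: dict[int, Exception] = {}
    prev: GlobalFitResult | None = None
    for K in range(1, K_max + 1):
        init = None
        if prev is not None:
            extra_center = _spawn_center(prev)
            init = {
                "centers": np.append(prev.centers, extra_center),
                "widths": np.append(prev.widths, 0.3),
                "populations": np.hstack(
                    [
                        prev.populations * (1.0 - 1e-3),
                        np.full((prev.populations.shape[0], 1), 1e-3),
                    ]
                ),
            }
        try:
            results[K] = fit_global(conditions, K, init=init, **kwargs)
            prev = results[K]
        except FitError as exc:
            errors[K] = exc
    if not results:
        raise FitError(f"all candidate models failed: {errors}")
    crit = {K: res.criterion_values[K] for K, res in results.items()}
    best_K = min(sorted(crit), key=lambda K: (crit[K], K))
    best = results[best_K]
    best.criterion_values = dict(sorted(crit.items()))
    best.objectives = {K: results[K].objective for K in sorted(results)}
    return best


def _spawn_center(prev: GlobalFitResult) -> float:
    """Place a new trial component at the largest gap of the existing ones."""
    grid = prev.grid
    anchors = np.concatenate([[grid.r_min], np.sort(prev.centers), [grid.r_max]])
    gaps = np.diff(anchors)
    i = int(np.argmax(gaps))
    return float(0.5 * (anchors[i] + anchors[i + 1]))


# ----------------------------------------------------- uncertainty reporting


def _shape_param_indices(result: GlobalFitResult, condition: int) -> np.ndarray:
    lay = result._layout
    idx = list(range(lay.centers.start, lay.centers.stop))
    idx += list(range(lay.widths.start, lay.widths.stop))
    if lay.K > 1:
        idx += list(range(lay.logits[condition].start, lay.logits[condition].stop))
    return np.array(idx, dtype=int)


def confidence_band(
    result: GlobalFitResult, level: float = 2.0, condition: int | str = 0
):
    """Pointwise ±level·σ envelope on P(r) by delta-method propagation.

    Returns (lower, upper) arrays on the fit grid; the lower bound is
    clipped at zero.
    """
    c = result._resolve_condition(condition)
    if result._cov is None:
        raise FitError("covariance unavailable; use a bootstrap fallback")
    lay = result._layout
    theta = result._theta
    r = result.grid.values
    centers = theta[lay.centers]
    widths = theta[lay.widths]
    phi, dphi_dr0, dphi_ds = _component_basis(r, centers, widths, result.grid.step)
    a = (
        _softmax_populations(theta[lay.logits[c]])
        if lay.K > 1
        else np.array([1.0])
    )
    P = a @ phi
    # gradient of P(r) wrt (centers, widths, logits_c)
    G = np.zeros((r.size, lay.n_params))
    for k in range(lay.K):
        G[:, lay.centers.start + k] = a[k] * dphi_dr0[k]
        G[:, lay.widths.start + k] = a[k] * dphi_ds[k]
    if lay.K > 1:
        for j in range(lay.K - 1):
            G[:, lay.logits[c].start + j] = a[j] * (phi[j] - P)
    var = np.einsum("ip,pq,iq->i", G, result._cov, G)
    se = np.sqrt(np.maximum(var, 0.0))
    return np.maximum(P - level * se, 0.0), P + level * se


def bootstrap_band(
    result: GlobalFitResult,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 2.0,
    condition: int | str = 0,
):
    """Parametric-bootstrap ±level·σ band on P(r).

    Synthetic noisy datasets are drawn from the fitted model with the
    per-trace noise estimates, refitted (warm-started at the solution), and
    the pointwise standard deviation of the refitted P(r) defines the band.
    Seeded, and independent of the delta-method propagation.
    """
    from .forward import DipolarTrace  # runtime import keeps module load light

    c = result._resolve_condition(condition)
    if result._traces is None:
        raise FitError("result carries no traces; refit before bootstrapping")
    rng = np.random.default_rng(seed)
    lay = result._layout
    init = {
        "centers": result._theta[lay.centers],
        "widths": result._theta[lay.widths],
        "populations": np.vstack(
            [
                _softmax_populations(result._theta[lay.logits[cc]])
                if lay.K > 1
                else np.array([1.0])
                for cc in range(lay.n_cond)
            ]
        ),
    }
    r = result.grid.values
    wr = np.full(r.size, result.grid.step)
    wr[0] = wr[-1] = 0.5 * result.grid.step
    helper = GlobalGaussianFitter(n_components=lay.K, grid=result.grid)
    kernels = [dipolar_kernel(tr.t, result.grid) * wr for tr in result._traces]
    clean = helper._residuals(
        result._theta,
        lay,
        result._cond_index,
        r,
        result.grid.step,
        kernels,
        [np.zeros_like(tr.V) for tr in result._traces],
        [tr.t for tr in result._traces],
    )
    edges = np.concatenate([[0], np.cumsum(result.n_points)])
    clean_per_trace = [clean[edges[i] : edges[i + 1]] for i in range(len(kernels))]

    densities = []
    boot_fitter = GlobalGaussianFitter(
        n_components=lay.K, grid=result.grid, n_restarts=1
    )
    for _ in range(n_boot):
        traces = []
        for t_idx, tr in enumerate(result._traces):
            noise = rng.normal(0.0, result.noise_sigmas[t_idx], tr.V.shape)
            traces.append(
                DipolarTrace(tr.t.copy(), clean_per_trace[t_idx] + noise, dict(tr.meta))
            )
        try:
            boot_fitter.fit(ConditionSet(traces), init=init)
        except FitError:
            continue
        densities.append(boot_fitter.result_.distribution(c).density)
    if len(densities) < max(10, n_boot // 4):
        raise FitError("too few successful bootstrap refits")
    densities = np.asarray(densities)
    P = result.distribution(c).density
    se = densities.std(axis=0, ddof=1)
    return np.maximum(P - level * se, 0.0), P + level * se


def state_population(
    result: GlobalFitResult, selector, condition: int | str = 0
) -> tuple[float, float]:
    """Population of one fitted component with its 2σ uncertainty.

    `selector` is either a sorted-component index or an (r_lo, r_hi) center
    window in nm that must match exactly one component.
    """
    c = result._resolve_condition(condition)
    if isinstance(selector, (tuple, list)) and len(selector) == 2:
        lo, hi = selector
        hits = [
            k for k, r0 in enumerate(result.centers) if lo <= r0 <= hi
        ]
        if len(hits) != 1:
            raise ValueError(
                f"center window [{lo}, {hi}] nm matches {len(hits)} components"
            )
        k_sorted = hits[0]
    else:
        k_sorted = int(selector)
        if not (0 <= k_sorted < result.n_components):
            raise ValueError(f"component index {k_sorted} out of range")
    value = float(result.populations[c, k_sorted])
    # uncertainty via softmax gradient in logit space
    if result.n_components == 1 or result._cov is None:
        return value, 0.0
    lay = result._layout
    k_raw = int(result._order[k_sorted])
    theta = result._theta
    a_raw = _softmax_populations(theta[lay.logits[c]])
    g = np.zeros(lay.n_params)
    for j in range(lay.K - 1):
        g[lay.logits[c].start + j] = a_raw[k_raw] * ((1.0 if j == k_raw else 0.0) - a_raw[j])
    var = float(g @ result._cov @ g)
    return value, 2.0 * np.sqrt(max(var, 0.0))
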