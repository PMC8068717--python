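"""Hierarchical Poisson (BYM) model for area counts, fitted by MCMC.

The model for observed counts with known offsets (expected counts from
indirect standardization) is

    O_i ~ Poisson(E_i * theta_i),
    log theta_i = alpha + x_i' beta + u_i + v_i,

with an intrinsic conditional autoregressive (ICAR) prior on the
structured effects u — a pairwise-difference Gaussian penalising
disagreement between neighbouring areas, improper with one flat direction
per connected component, identified by a sum-to-zero constraint — and iid
Normal(0, 1/tau_v) unstructured effects v.  Precisions carry Gamma(a, b)
priors (defaults a=1, b=5e-5), beta ~ Normal(0, 1000 I), alpha flat.

Inference is by MCMC: conjugate Gibbs updates for both precisions,
adaptive single-site random-walk Metropolis for every u_i and v_i (u
sites swept in graph-colouring order so that each colour class updates as
conditionally independent sites, vectorised), and an adaptive joint
random-walk for (alpha, beta).  u is re-centred to sum to zero per
connected component after every sweep with alpha absorbing the shift.

Usage follows the Model/Results convention::

    model = BYMModel(observed, expected, design, design_columns, graph)
    res = model.fit(MCMCConfig(seed=1))
    res.rate_ratios(); res.smoothed_smr(); res.summary()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph import AreaGraph

logger = logging.getLogger(__name__)

__all__ = [
    "BYMSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "BYMModel",
    "BYMResults",
    "icar_quadratic",
    "icar_precision",
    "sample_tau",
]


# --------------------------------------------------------------------------
# ICAR primitives
# --------------------------------------------------------------------------

def icar_precision(graph: AreaGraph) -> sp.csr_matrix:
    """ICAR precision structure Q = D - W (degree minus adjacency).

    Symmetric, rows sum to zero; rank n minus the number of connected
    components.
    """
    n = graph.n_areas
    ei, ej = graph.edge_index_arrays()
    rows = np.concatenate([ei, ej])
    cols = np.concatenate([ej, ei])
    w = sp.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    ).tocsr()
    d = sp.diags(np.asarray(w.sum(axis=1)).ravel())
    return (d - w).tocsr()


def icar_quadratic(u: np.ndarray, graph: AreaGraph) -> float:
    """Pairwise-difference penalty S = sum over edges (u_i - u_j)^2."""
    u = np.asarray(u, float)
    if u.shape != (graph.n_areas,):
        raise ValueError(
            f"u has length {u.shape}, graph has {graph.n_areas} areas"
        )
    ei, ej = graph.edge_index_arrays()
    return float(np.sum((u[ei] - u[ej]) ** 2))


def sample_tau(
    field_values: np.ndarray,
    graph: AreaGraph | None,
    prior: tuple[float, float],
    rng: np.random.Generator,
) -> float:
    """Draw a precision from its conjugate Gamma full conditional.

    For the structured field (``graph`` given) the conditional is
    Gamma(a + (n - c)/2, b + S/2) with S the ICAR quadratic form and c
    the number of connected components; for the unstructured field
    (``graph`` is None) it is Gamma(a + n/2, b + sum(v^2)/2).
    """
    a, b = prior
    x = np.asarray(field_values, float)
    n = x.size
    if graph is not None:
        s = icar_quadratic(x, graph)
        shape = a + (n - graph.n_components) / 2.0
    else:
        s = float(np.sum(x**2))
        shape = a + n / 2.0
    if s < 0:
        raise ValueError("negative quadratic form")
    return float(rng.gamma(shape, 1.0 / (b + s / 2.0)))


# --------------------------------------------------------------------------
# Specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BYMSpec:
    """Priors and structure switches for the BYM model.

    tau_a, tau_b : Gamma(shape, rate) hyperprior on both precisions.
    beta_prior_var : variance of the Normal(0, .) prior on each beta.
    include_* : allow reduced models (pure heterogeneity, toy posteriors).
    fixed_tau_* : pin a precision instead of sampling it.
    """

    tau_a: float = 1.0
    tau_b: float = 5e-5
    beta_prior_var: float = 1000.0
    include_intercept: bool = True
    include_structured: bool = True
    include_unstructured: bool = True
    fixed_tau_u: float | None = None
    fixed_tau_v: float | None = None

    def __post_init__(self):
        if self.tau_a <= 0 or self.tau_b <= 0:
            raise ValueError("Gamma hyperparameters must be positive")
        if self.beta_prior_var <= 0:
            raise ValueError("beta prior variance must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler schedule; the seed is mandatory for reproducibility."""

    seed: int
    chains: int = 2
    iterations: int = 3000
    burn_in: int = 1000
    thin: int = 1
    adapt_window: int = 50
    target_accept_single: float = 0.44
    target_accept_joint: float = 0.234

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained MCMC samples, shaped (chains, draws[, dim])."""

    alpha: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    tau_u: np.ndarray
    tau_v: np.ndarray
    beta_names: tuple[str, ...] = ()
    area_ids: tuple[str, ...] = ()
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0] * self.alpha.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains flattened into one axis."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])


class MCMCDivergenceError(RuntimeError):
    """Sampler reached a non-finite log-posterior; carries the state."""

    def __init__(self, message, state):
        super().__init__(message)
        self.state = state


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------

class BYMModel:
    """Poisson count model with ICAR + iid area random effects.

    Parameters
    ----------
    observed, expected
        Per-area counts and standardization offsets.  Areas with zero
        expected count cannot contribute a finite rate and are dropped
        from the likelihood with a warning.
    design, design_columns
        Optional covariate design.  A column named "intercept" is
        stripped: the intercept is the separately handled flat-prior
        alpha.
    graph
        Area adjacency for the ICAR prior; required when the spec
        includes structured effects.
    """

    def __init__(
        self,
        observed,
        expected,
        design: np.ndarray | None = None,
        design_columns: tuple[str, ...] | None = None,
        graph: AreaGraph | None = None,
        spec: BYMSpec = BYMSpec(),
        area_ids: tuple[str, ...] | None = None,
    ):
        O = np.asarray(observed, float)
        E = np.asarray(expected, float)
        if O.shape != E.shape:
            raise ValueError("observed/expected length mismatch")
        if (O < 0).any() or (E < 0).any():
            raise ValueError("negative counts or offsets")
        n_all = O.size
        if area_ids is None:
            area_ids = tuple(str(i) for i in range(n_all))
        keep = E > 0
        if not keep.all():
            dropped = [a for a, k in zip(area_ids, keep) if not k]
            logger.warning(
                "dropping %d area(s) with zero expected count: %s",
                len(dropped),
                dropped[:10],
            )
            if graph is not None:
                raise ValueError(
                    "zero-expected areas must be removed from the graph "
                    "before model construction"
                )
        self.observed = O[keep]
        self.expected = E[keep]
        self.area_ids = tuple(a for a, k in zip(area_ids, keep) if k)
        self.dropped_areas = tuple(a for a, k in zip(area_ids, keep) if not k)
        self.spec = spec
        self.graph = graph

        if design is not None:
            design = np.asarray(design, float)
            if design_columns is None:
                design_columns = tuple(
                    f"x{j}" for j in range(design.shape[1])
                )
            cols = [
                j for j, name in enumerate(design_columns) if name != "intercept"
            ]
            self.design = design[np.ix_(np.where(keep)[0], cols)]
            self.design_columns = tuple(design_columns[j] for j in cols)
        else:
            self.design = np.zeros((self.observed.size, 0))
            self.design_columns = ()

        if spec.include_structured:
            if graph is None:
                raise ValueError("structured effects require an area graph")
            if graph.n_areas != self.observed.size:
                raise ValueError("graph size does not match data")

        self.n = self.observed.size
        self.p = self.design.shape[1]
        if graph is not None:
            self._edge_i, self._edge_j = graph.edge_index_arrays()
            self._W = self._adjacency_matrix(graph)
            self._deg = graph.degrees().astype(float)
            self._colors = self._color_classes(graph)
            self._components = [
                np.where(np.asarray(graph.component_labels) == c)[0]
                for c in sorted(set(graph.component_labels))
            ]
        self._logfact = None  # lazily computed log(O!) for full log-posterior

    @classmethod
    def from_tables(
        cls,
        observed: pd.Series,
        expected: pd.Series,
        graph: AreaGraph,
        design: np.ndarray | None = None,
        design_columns: tuple[str, ...] | None = None,
        spec: BYMSpec = BYMSpec(),
    ) -> "BYMModel":
        """Build from pandas Series aligned to ``graph.area_ids``."""
        O = observed.reindex(list(graph.area_ids))
        E = expected.reindex(list(graph.area_ids))
        if O.isna().any() or E.isna().any():
            raise ValueError("observed/expected missing for some graph areas")
        return cls(
            O.to_numpy(), E.to_numpy(), design, design_columns, graph, spec,
            area_ids=graph.area_ids,
        )

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _adjacency_matrix(graph: AreaGraph) -> sp.csr_matrix:
        n = graph.n_areas
        ei, ej = graph.edge_index_arrays()
        rows = np.concatenate([ei, ej])
        cols = np.concatenate([ej, ei])
        return sp.coo_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(n, n)
        ).tocsr()

    @staticmethod
    def _color_classes(graph: AreaGraph) -> list[np.ndarray]:
        import networkx as nx

        coloring = nx.greedy_color(graph.to_networkx(), strategy="largest_first")
        idx = graph.index
        classes: dict[int, list[int]] = {}
        for area, color in coloring.items():
            classes.setdefault(color, []).append(idx[area])
        return [np.array(sorted(ix)) for _, ix in sorted(classes.items())]

    # -- log posterior -----------------------------------------------------
    def log_posterior(self, state: dict) -> float:
        """Log posterior density up to an additive constant.

        ``state`` holds alpha, beta, u, v, tau_u, tau_v (unused blocks may
        be zero).  Poisson likelihood + ICAR pseudo-density
        (n - c)/2 log tau_u - tau_u S_u / 2 + iid normal density for v +
        Gamma priors on the sampled precisions + Normal prior on beta.
        """
        alpha = float(state.get("alpha", 0.0))
        beta = np.asarray(state.get("beta", np.zeros(self.p)), float)
        u = np.asarray(state.get("u", np.zeros(self.n)), float)
        v = np.asarray(state.get("v", np.zeros(self.n)), float)
        vals = np.concatenate([[alpha], beta, u, v])
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite state")
        eta = alpha + self.design @ beta + u + v
        lp = float(np.sum(self.observed * eta - self.expected * np.exp(eta)))
        spec = self.spec
        if spec.include_structured:
            tau_u = float(state["tau_u"])
            s_u = float(np.sum((u[self._edge_i] - u[self._edge_j]) ** 2))
            c = self.graph.n_components
            lp += (self.n - c) / 2.0 * np.log(tau_u) - tau_u * s_u / 2.0
            if spec.fixed_tau_u is None:
                lp += (spec.tau_a - 1.0) * np.log(tau_u) - spec.tau_b * tau_u
        if spec.include_unstructured:
            tau_v = float(state["tau_v"])
            lp += self.n / 2.0 * np.log(tau_v) - tau_v * np.sum(v**2) / 2.0
            if spec.fixed_tau_v is None:
                lp += (spec.tau_a - 1.0) * np.log(tau_v) - spec.tau_b * tau_v
        if self.p:
            lp += -np.sum(beta**2) / (2.0 * spec.beta_prior_var)
        return lp

    # -- sampling ----------------------------------------------------------
    def fit(self, config: MCMCConfig) -> "BYMResults":
        """Run the sampler and return a results wrapper."""
        seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
        chains = [self._run_chain(config, np.random.default_rng(s)) for s in seeds]
        stack = {
            k: np.stack([c[k] for c in chains])
            for k in ("alpha", "beta", "u", "v", "tau_u", "tau_v")
        }
        accept = {
            k: float(np.mean([c["accept"][k] for c in chains]))
            for k in chains[0]["accept"]
        }
        draws = PosteriorDraws(
            **stack,
            beta_names=self.design_columns,
            area_ids=self.area_ids,
            accept_rates=accept,
        )
        return BYMResults(self, draws, config)

    def _run_chain(self, cfg: MCMCConfig, rng: np.random.Generator) -> dict:
        spec = self.spec
        n, p = self.n, self.p
        O, E = self.observed, self.expected

        alpha = float(np.log(max(O.sum(), 0.5) / E.sum())) if spec.include_intercept else 0.0
        beta = np.zeros(p)
        u = np.zeros(n)
        v = np.zeros(n)
        tau_u = spec.fixed_tau_u if spec.fixed_tau_u is not None else 10.0
        tau_v = spec.fixed_tau_v if spec.fixed_tau_v is not None else 10.0

        log_s_u = np.full(n, np.log(0.5))
        log_s_v = np.full(n, np.log(0.5))
        d = 1 + p if spec.include_intercept else p
        log_s_ab = np.log(2.38 / max(np.sqrt(d), 1.0))
        log_s_av = np.log(0.1)
        log_s_b = np.full(p, np.log(0.1))
        self._design_nz = [np.nonzero(self.design[:, j])[0] for j in range(p)]
        chol_ab = np.eye(d) if d else None
        ab_history = []

        # interweaving step: with w = u + v held fixed (likelihood
        # invariant), u | w, tau_u, tau_v is Gaussian with precision
        # P = tau_u Q + tau_v I, constrained to sum to zero per component
        # (conditioning by kriging); redrawing it each sweep decouples the
        # u/v split from the slow single-site dynamics.
        interweave = (
            spec.include_structured and spec.include_unstructured and n <= 1500
        )
        if interweave:
            # one-time eigendecomposition Q = V diag(lam) V'; in the
            # eigenbasis the conditional is independent per coordinate and
            # the sum-to-zero constraint is exactly "null coordinates = 0"
            q_dense = np.diag(self._deg) - self._W.toarray()
            q_lam, q_vec = np.linalg.eigh(q_dense)
            q_null = q_lam < max(q_lam[-1], 1.0) * 1e-10

        # covariate/field shift moves: beta shifts along a direction g
        # while u compensates, keeping eta invariant, so only the priors
        # enter the acceptance ratio.  Directions: each coordinate, plus
        # one collective trend across the decile indicators (the slowest
        # confounded mode on a smooth density gradient).
        shift_move = spec.include_structured and spec.include_intercept and p > 0
        if shift_move:
            dirs = [np.eye(p)[j] for j in range(p)]
            decile_cols = [
                j for j, c in enumerate(self.design_columns)
                if c.startswith("decile_")
            ]
            if len(decile_cols) > 1:
                trend = np.zeros(p)
                ramp = np.arange(1, len(decile_cols) + 1, dtype=float)
                trend[decile_cols] = ramp / np.linalg.norm(ramp)
                dirs.append(trend)
            shift_dirs = np.array(dirs)  # (m, p)
            x_profiles = self.design @ shift_dirs.T  # (n, m)
            x_edge_diff = (
                x_profiles[self._edge_i] - x_profiles[self._edge_j]
            )  # (n_edges, m)
            x_edge_sq = np.sum(x_edge_diff**2, axis=0)
            x_mean = x_profiles.mean(axis=0)
            g_norm_sq = np.sum(shift_dirs**2, axis=1)
            log_s_shift = np.full(len(dirs), np.log(0.1))

        n_keep = -(-(cfg.iterations - cfg.burn_in) // cfg.thin)
        out = {
            "alpha": np.empty(n_keep),
            "beta": np.empty((n_keep, p)),
            "u": np.empty((n_keep, n)),
            "v": np.empty((n_keep, n)),
            "tau_u": np.empty(n_keep),
            "tau_v": np.empty(n_keep),
        }
        acc_counts = {"u": 0.0, "v": 0.0, "ab": 0.0}
        n_sweeps = {"u": 0, "v": 0, "ab": 0}

        xb = self.design @ beta
        kept = 0
        for t in range(cfg.iterations):
            adapting = t < cfg.burn_in
            step_scale = min(0.05, (t + 1) ** -0.5)

            # ---- v: iid sites, conditionally independent, vectorised ----
            if spec.include_unstructured:
                base = alpha + xb + u
                prop = v + np.exp(log_s_v) * rng.standard_normal(n)
                delta = (
                    O * (prop - v)
                    - E * np.exp(base) * (np.exp(prop) - np.exp(v))
                    - tau_v / 2.0 * (prop**2 - v**2)
                )
                acc = np.log(rng.random(n)) < delta
                v = np.where(acc, prop, v)
                if adapting:
                    log_s_v += step_scale * (acc - cfg.target_accept_single)
                acc_counts["v"] += acc.mean()
                n_sweeps["v"] += 1

            # ---- u: single-site Metropolis swept by colour class --------
            if spec.include_structured:
                base = alpha + xb + v
                acc_total = 0.0
                for cls in self._colors:
                    wu = self._W @ u  # neighbour sums (u fixed outside class)
                    ui = u[cls]
                    prop = ui + np.exp(log_s_u[cls]) * rng.standard_normal(cls.size)
                    dlike = O[cls] * (prop - ui) - E[cls] * np.exp(base[cls]) * (
                        np.exp(prop) - np.exp(ui)
                    )
                    dicar = -tau_u / 2.0 * (
                        self._deg[cls] * (prop**2 - ui**2)
                        - 2.0 * (prop - ui) * wu[cls]
                    )
                    acc = np.log(rng.random(cls.size)) < dlike + dicar
                    u[cls] = np.where(acc, prop, ui)
                    if adapting:
                        log_s_u[cls] += step_scale * (
                            acc - cfg.target_accept_single
                        )
                    acc_total += acc.sum()
                acc_counts["u"] += acc_total / n
                n_sweeps["u"] += 1

                if interweave:
                    w = u + v
                    dprec = tau_u * q_lam + tau_v
                    coef = (tau_v * (q_vec.T @ w) + np.sqrt(dprec)
                            * rng.standard_normal(n)) / dprec
                    coef[q_null] = 0.0
                    u = q_vec @ coef
                    v = w - u

                # sum-to-zero per component; alpha absorbs the global shift
                shift = u.mean()
                if spec.include_intercept:
                    alpha += shift
                u -= shift
                if len(self._components) > 1:
                    for comp in self._components:
                        u[comp] -= u[comp].mean()

            # ---- precisions: conjugate Gibbs ----------------------------
            if spec.include_structured and spec.fixed_tau_u is None:
                tau_u = sample_tau(u, self.graph, (spec.tau_a, spec.tau_b), rng)
            if spec.include_unstructured and spec.fixed_tau_v is None:
                tau_v = sample_tau(v, None, (spec.tau_a, spec.tau_b), rng)

            # ---- beta: single-coordinate random walk --------------------
            if p:
                eta_cur = alpha + xb + u + v
                for j in range(p):
                    idx = self._design_nz[j]
                    dx = self.design[idx, j]
                    delta_b = np.exp(log_s_b[j]) * rng.standard_normal()
                    step = delta_b * dx
                    dlog = float(
                        np.sum(
                            O[idx] * step
                            - E[idx] * np.exp(eta_cur[idx]) * np.expm1(step)
                        )
                    ) - (2.0 * beta[j] * delta_b + delta_b**2) / (
                        2.0 * spec.beta_prior_var
                    )
                    acc_b = np.isfinite(dlog) and np.log(rng.random()) < dlog
                    if acc_b:
                        beta[j] += delta_b
                        eta_cur[idx] += step
                        xb[idx] += step
                    if adapting:
                        log_s_b[j] += step_scale * (
                            float(acc_b) - cfg.target_accept_single
                        )

            # ---- (alpha, beta): adaptive joint random walk --------------
            if d:
                cur = np.concatenate(([alpha] if spec.include_intercept else [], beta))
                z = chol_ab @ rng.standard_normal(d)
                prop = cur + np.exp(log_s_ab) * z
                if spec.include_intercept:
                    alpha_p, beta_p = prop[0], prop[1:]
                else:
                    alpha_p, beta_p = alpha, prop
                eta0 = alpha + xb + u + v
                xb_p = self.design @ beta_p
                eta1 = alpha_p + xb_p + u + v
                delta = float(
                    np.sum(O * (eta1 - eta0) - E * (np.exp(eta1) - np.exp(eta0)))
                )
                if p:
                    delta += float(
                        (np.sum(beta**2) - np.sum(beta_p**2))
                        / (2.0 * spec.beta_prior_var)
                    )
                accepted = np.isfinite(delta) and np.log(rng.random()) < delta
                if accepted:
                    alpha, beta, xb = float(alpha_p), beta_p, xb_p
                if adapting:
                    log_s_ab += step_scale * (
                        float(accepted) - cfg.target_accept_joint
                    )
                    ab_history.append(
                        np.concatenate(
                            ([alpha] if spec.include_intercept else [], beta)
                        )
                    )
                    if (
                        d > 1
                        and t % cfg.adapt_window == cfg.adapt_window - 1
                        and len(ab_history) > 10 * d
                    ):
                        cov = np.cov(np.array(ab_history[-2000:]).T)
                        cov += 1e-8 * np.eye(d)
                        chol_ab = np.linalg.cholesky(cov)
                acc_counts["ab"] += float(accepted)
                n_sweeps["ab"] += 1

            # ---- likelihood-invariant alpha <-> v level shift ------------
            if spec.include_intercept and spec.include_unstructured:
                delta_a = np.exp(log_s_av) * rng.standard_normal()
                log_r = -tau_v / 2.0 * (n * delta_a**2 - 2.0 * delta_a * v.sum())
                acc_av = np.log(rng.random()) < log_r
                if acc_av:
                    alpha += delta_a
                    v -= delta_a
                if adapting:
                    log_s_av += step_scale * (
                        float(acc_av) - cfg.target_accept_single
                    )

            # ---- likelihood-invariant beta_j <-> u shifts ----------------
            if shift_move:
                du_e = u[self._edge_i] - u[self._edge_j]
                for j in range(shift_dirs.shape[0]):
                    delta_j = np.exp(log_s_shift[j]) * rng.standard_normal()
                    # change in ICAR penalty for u -> u - delta*(x_g - mean)
                    d_s = (
                        -2.0 * delta_j * float(du_e @ x_edge_diff[:, j])
                        + delta_j**2 * x_edge_sq[j]
                    )
                    log_r = -tau_u / 2.0 * d_s - (
                        2.0 * delta_j * float(beta @ shift_dirs[j])
                        + delta_j**2 * g_norm_sq[j]
                    ) / (2.0 * spec.beta_prior_var)
                    acc_shift = np.log(rng.random()) < log_r
                    if acc_shift:
                        beta += delta_j * shift_dirs[j]
                        u -= delta_j * (x_profiles[:, j] - x_mean[j])
                        alpha -= delta_j * x_mean[j]
                        du_e -= delta_j * x_edge_diff[:, j]
                    if adapting:
                        log_s_shift[j] += step_scale * (
                            float(acc_shift) - cfg.target_accept_single
                        )
                xb = self.design @ beta

            if not np.all(np.isfinite([alpha, tau_u, tau_v])) or not (
                np.all(np.isfinite(u)) and np.all(np.isfinite(v))
            ):
                raise MCMCDivergenceError(
                    f"non-finite state at iteration {t}",
                    {"alpha": alpha, "beta": beta, "u": u, "v": v,
                     "tau_u": tau_u, "tau_v": tau_v, "iteration": t},
                )

            if t >= cfg.burn_in and (t - cfg.burn_in) % cfg.thin == 0:
                out["alpha"][kept] = alpha
                out["beta"][kept] = beta
                out["u"][kept] = u
                out["v"][kept] = v
                out["tau_u"][kept] = tau_u
                out["tau_v"][kept] = tau_v
                kept += 1

        out["accept"] = {
            k: acc_counts[k] / max(n_sweeps[k], 1) for k in acc_counts
        }
        return out


# --------------------------------------------------------------------------
# Results
# --------------------------------------------------------------------------

class BYMResults:
    """Posterior draws plus summaries: rate ratios, smoothed/residual SMRs."""

    def __init__(self, model: BYMModel, draws: PosteriorDraws, config: MCMCConfig):
        self.model = model
        self.draws = draws
        self.config = config

    # -- coefficient summaries ---------------------------------------------
    def rate_ratios(
        self, min_ess: float = 200.0, ci: float = 0.95
    ) -> pd.DataFrame:
        """Rate ratios exp(beta): posterior median, equal-tailed CI, flag.

        A coefficient is flagged significant when its CI excludes 1.
        Quantities with fewer than ``min_ess`` effective samples carry a
        low_ess flag (the estimate is reported but unreliable).
        """
        lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
        beta = self.draws.stacked("beta")
        rows = []
        ess = self._ess_matrix(self.draws.beta)
        for j, name in enumerate(self.draws.beta_names):
            rr = np.exp(beta[:, j])
            lo, med, hi = np.quantile(rr, [lo_q, 0.5, hi_q])
            low_ess = ess[j] < min_ess
            if low_ess:
                logger.warning(
                    "coefficient %s has only %.0f effective samples", name, ess[j]
                )
            rows.append(
                {
                    "coefficient": name,
                    "rr": med,
                    "ci_low": lo,
                    "ci_high": hi,
                    "significant": bool(lo > 1.0 or hi < 1.0),
                    "ess": ess[j],
                    "low_ess": bool(low_ess),
                }
            )
        return pd.DataFrame(rows)

    def _ess_matrix(self, arr: np.ndarray) -> np.ndarray:
        import arviz as az

        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.shape[2] == 0:
            return np.array([])
        ds = az.convert_to_dataset(arr)
        return np.atleast_1d(az.ess(ds)["x"].values)

    # -- area summaries ------------------------------------------------------
    def smoothed_smr(self) -> pd.Series:
        """Posterior median of theta_i = exp(alpha + u_i + v_i) per area.

        Meant for the covariate-free model; with covariates present this
        is the fitted relative risk net of the covariate term.
        """
        theta = np.exp(
            self.draws.stacked("alpha")[:, None]
            + self.draws.stacked("u")
            + self.draws.stacked("v")
        )
        return pd.Series(
            np.median(theta, axis=0), index=list(self.draws.area_ids), name="smr"
        )

    def residual_smr(self) -> pd.Series:
        """Posterior median of exp(u_i + v_i): risk the covariates leave."""
        r = np.exp(self.draws.stacked("u") + self.draws.stacked("v"))
        return pd.Series(
            np.median(r, axis=0), index=list(self.draws.area_ids), name="residual_smr"
        )

    def summarize(self, mode: str = "smoothed") -> dict:
        """Bundle of the summaries the mapping pipeline consumes."""
        if mode not in {"smoothed", "adjusted"}:
            raise ValueError("mode must be 'smoothed' or 'adjusted'")
        out = {
            "rate_ratios": self.rate_ratios(),
            "smoothed_smr": self.smoothed_smr(),
        }
        if mode == "adjusted":
            out["residual_smr"] = self.residual_smr()
        return out

    # -- diagnostics ---------------------------------------------------------
    def diagnostics(self, rhat_threshold: float = 1.05) -> pd.DataFrame:
        """Split-R̂ and effective sample size for the monitored parameters.

        Monitors alpha, every beta, both precisions.  With a single chain
        the two halves serve as pseudo-chains for R̂.
        """
        import arviz as az

        draws = self.draws
        named = {"alpha": draws.alpha, "tau_u": draws.tau_u, "tau_v": draws.tau_v}
        for j, name in enumerate(draws.beta_names):
            named[name] = draws.beta[:, :, j]
        rows = []
        for name, arr in named.items():
            if not self._monitored(name):
                continue
            a = np.asarray(arr)
            if a.shape[0] == 1:  # split the single chain in half
                half = a.shape[1] // 2
                a = np.stack([a[0, :half], a[0, half : 2 * half]])
            ds = az.convert_to_dataset(a[:, :, None])
            rhat = np.asarray(az.rhat(ds)["x"].values).item()
            ess = np.asarray(
                az.ess(az.convert_to_dataset(np.asarray(arr)[:, :, None]))["x"].values
            ).item()
            rows.append({"parameter": name, "rhat": rhat, "ess": ess})
        df = pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])
        df["converged"] = df["rhat"] <= rhat_threshold
        return df

    def _monitored(self, name: str) -> bool:
        spec = self.model.spec
        if name == "alpha":
            return spec.include_intercept
        if name == "tau_u":
            return spec.include_structured and spec.fixed_tau_u is None
        if name == "tau_v":
            return spec.include_unstructured and spec.fixed_tau_v is None
        return True

    @property
    def converged(self) -> bool:
        diag = self.diagnostics()
        return bool(diag.empty or diag["converged"].all())

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "BYM hierarchical Poisson model",
            f"  areas: {self.model.n}   covariates: {self.model.p}",
            f"  chains: {self.config.chains}  draws/chain: "
            f"{(self.config.iterations - self.config.burn_in) // self.config.thin}",
            f"  acceptance: "
            + ", ".join(
                f"{k}={v:.2f}" for k, v in self.draws.accept_rates.items()
            ),
        ]
        rr = self.rate_ratios()
        if len(rr):
            lines.append("  rate ratios (posterior median, 95% CI):")
            for _, r in rr.iterrows():
                star = "*" if r["significant"] else " "
                lines.append(
                    f"    {r['coefficient']:>16s}: {r['rr']:.3f}{star} "
                    f"({r['ci_low']:.3f}, {r['ci_high']:.3f})"
                )
        diag = self.diagnostics()
        if not diag.empty:
            lines.append(
                f"  max split-Rhat: {diag['rhat'].max():.3f}  "
                f"min ESS: {diag['ess'].min():.0f}"
            )
        return "\n".join(lines)


def refit_with_prior(results: BYMResults, **spec_updates) -> BYMResults:
    """Refit the same data under altered hyperparameters (sensitivity)."""
    model = results.model
    new = BYMModel(
        model.observed,
        model.expected,
        np.column_stack([np.ones(model.n), model.design]) if model.p else None,
        ("intercept",) + model.design_columns if model.p else None,
        model.graph,
        replace(model.spec, **spec_updates),
        area_ids=model.area_ids,
    )
    return new.fit(results.config)
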