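"""Synthetic-data generation and the simulation study runner.

The generator reproduces the study design the model family was validated
under: L in {3, 4} latent traits, m in {3, 5} items per trait, orthogonal
or correlated traits, and a simple or slightly complex discrimination
structure.  Per trait, assigned discriminations run equidistantly from 0.2
to 0.3; intercepts are equidistant in [1.5, 3.5] and log-dispersions in
[-0.8, 0.8], both randomly permuted across items, so every dataset mixes
conditionally over- and underdispersed items.  In the slightly complex
structure, a quarter (ceil(m/4)) of each trait's items additionally receive
at least one weaker cross-loading on another trait.

The study runner fits, per generated dataset: the unpenalized model
(rotated by varimax and oblimin) and two BIC-tuned lasso paths — one with
orthogonal traits, one with the latent correlations plugged in from the
oblique rotation — and scores all four with the evaluation metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional

import numpy as np
import pandas as pd

from cmpirt import cmp
from cmpirt import em as _em
from cmpirt import lasso as _lasso
from cmpirt import metrics as _metrics
from cmpirt.em import FitConfig, ItemParameters, apply_constraints
from cmpirt.quadrature import LatentCovariance
from cmpirt.rotation import align_solution, oblimin, varimax

__all__ = [
    "SimCondition",
    "SimTruth",
    "build_lambda",
    "generate_dataset",
    "StudyConfig",
    "run_study",
    "condition_grid",
]

SLOPE_RANGE = (0.2, 0.3)
INTERCEPT_RANGE = (1.5, 3.5)
LOG_DISP_RANGE = (-0.8, 0.8)


@dataclass
class SimCondition:
    """One cell of the simulation design."""

    L: int = 3
    m: int = 3
    rho: float = 0.0
    structure: str = "simple"  # or "complex"
    N: int = 600
    seed: int = 0
    cross_value: float = 0.1
    cross_prob: float = 0.5

    def __post_init__(self):
        if self.structure not in ("simple", "complex"):
            raise ValueError("structure must be 'simple' or 'complex'")
        if self.N < 1:
            raise ValueError("N must be positive")
        if not 0 <= abs(self.rho) < 1:
            raise ValueError("rho must lie in (-1, 1)")

    @property
    def M(self) -> int:
        return self.L * self.m

    def label(self) -> str:
        return (
            f"L{self.L}_m{self.m}_r{self.rho:g}_{self.structure}_N{self.N}"
        )


@dataclass
class SimTruth:
    params: ItemParameters
    sigma: LatentCovariance
    theta: np.ndarray  # (N, L)


def build_lambda(
    L: int,
    m: int,
    structure: str = "simple",
    cross_value: float = 0.1,
    cross_prob: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """True discrimination matrix for one condition.

    Simple: item block l loads only on trait l, with the m slopes
    equidistant from 0.2 to 0.3.  Complex: the simple entries are kept and
    ceil(m/4) designated items per trait draw cross-loadings of size
    ``cross_value`` on each other trait with probability ``cross_prob``,
    with at least one cross-loading guaranteed per designated item.
    """
    M = L * m
    A = np.zeros((M, L))
    block = np.linspace(SLOPE_RANGE[0], SLOPE_RANGE[1], m)
    for l in range(L):
        A[l * m : (l + 1) * m, l] = block
    if structure == "complex":
        rng = np.random.default_rng(seed)
        n_cross = math.ceil(m / 4)
        for l in range(L):
            rows = rng.choice(np.arange(l * m, (l + 1) * m), n_cross, replace=False)
            others = [t for t in range(L) if t != l]
            for j in rows:
                hits = rng.random(L - 1) < cross_prob
                if not hits.any():
                    hits[rng.integers(L - 1)] = True
                for t, hit in zip(others, hits):
                    if hit:
                        A[j, t] = cross_value
    return A


def generate_dataset(cond: SimCondition, truth_overrides: Optional[dict] = None):
    """Simulate (Y, truth) under the model for one condition.

    theta_i ~ MVN(0, Sigma(rho)); mu_ij = exp(delta_j + a_j' theta_i);
    y_ij ~ CMP(mu_ij, nu_j).  Deterministic given the condition seed.
    """
    rng = np.random.default_rng(cond.seed)
    M = cond.M
    A = build_lambda(
        cond.L, cond.m, cond.structure, cond.cross_value, cond.cross_prob, cond.seed
    )
    delta = rng.permutation(np.linspace(*INTERCEPT_RANGE, M))
    log_disp = rng.permutation(np.linspace(*LOG_DISP_RANGE, M))
    overrides = truth_overrides or {}
    A = np.asarray(overrides.get("slopes", A), dtype=float)
    delta = np.asarray(overrides.get("intercepts", delta), dtype=float)
    log_disp = np.asarray(overrides.get("log_disp", log_disp), dtype=float)
    sigma = LatentCovariance.exchangeable(cond.L, cond.rho)
    theta = rng.multivariate_normal(np.zeros(cond.L), sigma.sigma, size=cond.N)
    mu = np.exp(delta[None, :] + theta @ A.T)
    Y = np.empty((cond.N, M), dtype=np.int64)
    nu = np.exp(log_disp)
    for j in range(M):
        Y[:, j] = cmp.sample(mu[:, j], nu[j], cond.N, rng)
    truth = SimTruth(
        params=ItemParameters(A, delta, log_disp), sigma=sigma, theta=theta
    )
    return Y, truth


METHODS = ("rotate_varimax", "rotate_oblimin", "lasso_ortho", "lasso_obli")


@dataclass
class StudyConfig:
    """Configuration of a study run (condition grid x trials)."""

    conditions: List[SimCondition] = field(default_factory=list)
    trials: int = 10
    seed: int = 1
    n_eta: int = 12
    fit: FitConfig = field(default_factory=FitConfig)

    def to_dict(self) -> dict:
        return {
            "conditions": [asdict(c) for c in self.conditions],
            "trials": self.trials,
            "seed": self.seed,
            "n_eta": self.n_eta,
            "fit": asdict(self.fit),
        }


def condition_grid(
    Ls=(3, 4), ms=(3, 5), rhos=(0.0, 0.5), structures=("simple", "complex"), N=600
) -> List[SimCondition]:
    """The fully crossed 16-condition design (2 x 2 x 2 x 2)."""
    return [
        SimCondition(L=L, m=m, rho=r, structure=s, N=N)
        for L in Ls
        for m in ms
        for r in rhos
        for s in structures
    ]


def _fit_trial(Y, truth, cond, config: StudyConfig):
    """All four methods on one dataset; returns {method: (A, phi, fit)}."""
    L = cond.L
    mask = apply_constraints(L, cond.M)
    unp = _em.fit(Y, L, config=config.fit, mask=mask)
    rot_v = varimax(unp.params.slopes)
    rot_o = oblimin(unp.params.slopes)
    sigma_obli = _lasso.sigma_plugin(unp.params.slopes)
    path_ortho = _lasso.tune_path(
        Y, L, config=config.fit, mask=mask, n_grid=config.n_eta, unpenalized=unp
    )
    unp_obli = _em.fit(Y, L, sigma=sigma_obli, config=config.fit, mask=mask,
                       start=unp.params)
    path_obli = _lasso.tune_path(
        Y, L, sigma=sigma_obli, config=config.fit, mask=mask,
        n_grid=config.n_eta, unpenalized=unp_obli,
    )
    out = {
        "rotate_varimax": (rot_v.loadings, rot_v.phi, unp),
        "rotate_oblimin": (rot_o.loadings, rot_o.phi, unp),
        "lasso_ortho": (
            path_ortho.selected_fit.params.slopes,
            np.eye(L),
            path_ortho.selected_fit,
        ),
        "lasso_obli": (
            path_obli.selected_fit.params.slopes,
            sigma_obli.sigma,
            path_obli.selected_fit,
        ),
    }
    return out, {"ortho": path_ortho, "obli": path_obli}


def _trial_records(cond, trial, methods, truth, mask):
    rows = []
    A_true = truth.params.slopes
    phi_true = truth.sigma.sigma
    for name, (A_hat, phi_hat, fit) in methods.items():
        rec = {
            "condition": cond.label(),
            "trial": trial,
            "method": name,
        }
        rec["cer"] = _metrics.cer(A_hat, A_true, mask)
        rec["n_zeros"] = int(np.sum(A_hat[mask.free()] == 0.0))
        gb, gr = _metrics.gram_offdiag_metrics(A_hat, phi_hat, A_true, phi_true)
        rec["gram_bias"] = gb
        rec["gram_rmse"] = gr
        rec["bias_intercepts"] = float(
            (fit.params.intercepts - truth.params.intercepts).mean()
        )
        rec["rmse_intercepts"] = float(
            np.sqrt(((fit.params.intercepts - truth.params.intercepts) ** 2).mean())
        )
        rec["bias_logdisp"] = float(
            (fit.params.log_disp - truth.params.log_disp).mean()
        )
        rec["rmse_logdisp"] = float(
            np.sqrt(((fit.params.log_disp - truth.params.log_disp) ** 2).mean())
        )
        rec["marginal_loglik"] = fit.marginal_loglik
        rec["converged"] = fit.converged
        rows.append(rec)
    return rows


def run_study(config: StudyConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full study grid; returns one tidy row per (condition, trial,
    method).  Per-trial failures are logged in the output (method 'failed')
    and excluded from the metric rows; everything is seeded from
    ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    rows = []
    for ci, cond in enumerate(config.conditions):
        mask = apply_constraints(cond.L, cond.M)
        for trial in range(config.trials):
            child = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(ci, trial)
            )
            seed = int(child.generate_state(1)[0] % (2**31))
            tcond = SimCondition(**{**asdict(cond), "seed": seed})
            Y, truth = generate_dataset(tcond)
            try:
                methods, _ = _fit_trial(Y, truth, tcond, config)
            except (FloatingPointError, np.linalg.LinAlgError) as err:
                rows.append(
                    {
                        "condition": cond.label(),
                        "trial": trial,
                        "method": "failed",
                        "error": str(err),
                    }
                )
                continue
            rows.extend(_trial_records(tcond, trial, methods, truth, mask))
            if progress:
                print(f"[{cond.label()}] trial {trial + 1}/{config.trials} done")
    return pd.DataFrame(rows)


def summarize_study(results: pd.DataFrame) -> pd.DataFrame:
    """Condition x method means of the per-trial metrics."""
    ok = results[results["method"] != "failed"]
    num = ok.select_dtypes("number").columns.difference(["trial"])
    return ok.groupby(["condition", "method"])[list(num)].mean().reset_index()
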