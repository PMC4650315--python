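"""Circular regression of transcript peak phase on TF-group binding scores.

Genes bound by different combinations of clock transcription factors peak at
characteristic circadian times: E-box activators (CLOCK/BMAL1/NPAS2) drive
dusk-phased expression, RRE regulators (REV-ERB alpha/beta, ROR alpha) and the
D-box repressor (E4BP4) dawn-phased expression.  The model captures this with
a von Mises GLM whose mean direction is linked to the three normalized
TF-group binding scores via a 2*arctan link:

    E(phi) = mu + 2*arctan(c_E*S_E + c_D*S_D + c_RRE*S_RRE)

with phi the peak phase and kappa a common concentration.  Fitting is by
maximum likelihood: for fixed mean structure the log-likelihood is linear in
kappa, so (mu, c) maximize the sum of cosines of the residuals (multi-start
quasi-Newton, since the arctan link can make the surface multimodal) and
kappa is then recovered by inverting A(kappa) = I1(kappa)/I0(kappa) at the
mean resultant length of the residuals.

All internal angles are radians; phases are reported in circadian-time (CT)
hours, 24 h = 2*pi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .registry import HitMatrix, Registry

__all__ = [
    "PhaseRecord",
    "CircularPhaseGLM",
    "CircularPhaseGLMResults",
    "tf_group_scores",
    "filter_and_pool_phases",
    "load_phase_table",
    "write_phase_table",
    "predict_phase",
    "rayleigh_test",
    "circular_median_ct",
    "tf_combo_summary",
    "wrap_ct",
    "ct_to_radians",
    "radians_to_ct",
    "circular_mean_ct",
    "vonmises_kappa_from_rbar",
]

HOURS_PER_CYCLE = 24.0
_RAD_PER_HOUR = 2.0 * np.pi / HOURS_PER_CYCLE

TF_GROUP_NAMES = ("ebox", "dbox", "rre")
SCORE_COLUMNS = ("s_e", "s_d", "s_rre")


def wrap_ct(hours) -> np.ndarray | float:
    """Wrap CT hours onto [0, 24)."""
    return np.mod(hours, HOURS_PER_CYCLE)


def ct_to_radians(hours) -> np.ndarray | float:
    return np.asarray(hours, dtype=float) * _RAD_PER_HOUR


def radians_to_ct(theta) -> np.ndarray | float:
    return np.mod(np.asarray(theta, dtype=float) / _RAD_PER_HOUR, HOURS_PER_CYCLE)


def circular_mean_ct(hours: Iterable[float]) -> float:
    theta = ct_to_radians(np.asarray(list(hours), dtype=float))
    return float(radians_to_ct(np.angle(np.exp(1j * theta).mean())))


def vonmises_kappa_from_rbar(rbar: float) -> float:
    """Invert the mean resultant length A(kappa) = I1(kappa)/I0(kappa)."""
    rbar = float(np.clip(rbar, 0.0, 1.0 - 1e-12))
    if rbar < 1e-12:
        return 1e-8

    def f(kappa):
        return special.i1e(kappa) / special.i0e(kappa) - rbar

    lo, hi = 1e-10, 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - rbar clipped below 1
            break
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


# ---------------------------------------------------------------------------
# Phase observations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseRecord:
    """One transcript rhythmicity call: gene, tissue, peak phase (CT hours,
    wrapped to [0, 24)) and the rhythm-detection FDR."""

    gene_id: str
    tissue: str
    phase_ct: float
    fdr: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase_ct", float(wrap_ct(self.phase_ct)))
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr {self.fdr} outside [0, 1]")


def filter_and_pool_phases(
    records: Sequence[PhaseRecord] | pd.DataFrame, fdr_cutoff: float = 0.05
) -> pd.DataFrame:
    """Keep significantly rhythmic records (fdr < cutoff) and pool them.

    Each surviving gene-tissue pair is one observation; observations are
    pooled across tissues without per-gene weighting.  Returns a DataFrame
    with columns gene_id, tissue, phase_ct (wrapped to [0, 24)).
    """
    if isinstance(records, pd.DataFrame):
        df = records[["gene_id", "tissue", "phase_ct", "fdr"]].copy()
    else:
        df = pd.DataFrame(
            [(r.gene_id, r.tissue, r.phase_ct, r.fdr) for r in records],
            columns=["gene_id", "tissue", "phase_ct", "fdr"],
        )
    kept = df[df["fdr"] < fdr_cutoff].copy()
    kept["phase_ct"] = wrap_ct(kept["phase_ct"].to_numpy(dtype=float))
    return kept[["gene_id", "tissue", "phase_ct"]].reset_index(drop=True)


def load_phase_table(path) -> pd.DataFrame:
    """Read a TSV with columns gene_id, tissue, phase_ct, fdr."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tissue": str})
    missing = [c for c in ("gene_id", "tissue", "phase_ct", "fdr") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing phase-table column(s) {missing}")
    return df


def write_phase_table(records: Sequence[PhaseRecord] | pd.DataFrame, path) -> None:
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            [(r.gene_id, r.tissue, r.phase_ct, r.fdr) for r in records],
            columns=["gene_id", "tissue", "phase_ct", "fdr"],
        )
    records.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# TF-group binding scores
# ---------------------------------------------------------------------------


def tf_group_scores(hits: HitMatrix, registry: Registry) -> pd.DataFrame:
    """Normalized per-gene binding scores S_E, S_D, S_RRE in [0, 1].

    Each group score is the weighted hit sum over the ChIP-seq datasets of
    that TF group divided by the group's maximum attainable score (6 for the
    E-box group of the built-in registry, since the weight-3 dataset counts
    with its weight; 1 for D-box; 5 for RRE).  PER/CRY ChIP-seq columns
    (tf_group "none") contribute to no group.
    """
    if hits.dataset_ids != registry.dataset_ids:
        raise ValueError("hit matrix columns do not match registry order")
    weights = registry.weights
    out = {}
    for name, col in zip(TF_GROUP_NAMES, SCORE_COLUMNS):
        mask = registry.group_mask(name)
        gmax = int(weights[mask].sum())
        if gmax == 0:
            raise ValueError(f"TF group {name!r} has no ChIP-seq datasets in the registry")
        out[col] = (hits.values[:, mask] @ weights[mask]) / gmax
    return pd.DataFrame(out, index=pd.Index(hits.gene_ids, name="gene_id"))


# ---------------------------------------------------------------------------
# The von Mises arctan-link GLM
# ---------------------------------------------------------------------------


class CircularPhaseGLM:
    """von Mises regression of circular phase on TF-group scores.

    Parameters
    ----------
    phases_ct : array-like
        Observed peak phases in CT hours (wrapped internally).
    exog : DataFrame or (n, k) array
        Regressors, one row per observation (typically the three TF-group
        scores s_e, s_d, s_rre).  Constant columns are detected at fit time,
        flagged unidentifiable and their coefficients fixed at 0.

    Use :meth:`from_dataframe` to assemble the design from pooled phase
    observations and a per-gene score table.
    """

    def __init__(self, phases_ct, exog, exog_names: Sequence[str] | None = None):
        phases_ct = np.asarray(phases_ct, dtype=float)
        if isinstance(exog, pd.DataFrame):
            if exog_names is None:
                exog_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if exog.shape[0] != phases_ct.shape[0]:
            raise ValueError(
                f"{phases_ct.shape[0]} phases but {exog.shape[0]} regressor rows"
            )
        if phases_ct.shape[0] < 5:
            raise ValueError("need at least 5 observations to fit")
        self.endog_ct = wrap_ct(phases_ct)
        self.theta = ct_to_radians(self.endog_ct)
        self.exog = exog
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{i}" for i in range(exog.shape[1])]
        )
        self.nobs = phases_ct.shape[0]

    @classmethod
    def from_dataframe(
        cls, observations: pd.DataFrame, scores: pd.DataFrame
    ) -> "CircularPhaseGLM":
        """Join pooled observations (gene_id, tissue, phase_ct) with per-gene
        TF-group scores (indexed by gene_id) into a model."""
        merged = observations.merge(
            scores, left_on="gene_id", right_index=True, how="inner"
        )
        cols = [c for c in SCORE_COLUMNS if c in merged.columns]
        if not cols:
            raise ValueError("score table has none of the expected columns s_e/s_d/s_rre")
        return cls(merged["phase_ct"].to_numpy(), merged[cols], exog_names=cols)

    # -- likelihood pieces --------------------------------------------------

    def _mean_angle(self, mu: float, coefs: np.ndarray) -> np.ndarray:
        return mu + 2.0 * np.arctan(self.exog @ coefs)

    def loglike(self, mu: float, coefs: np.ndarray, kappa: float) -> float:
        """von Mises log-likelihood at (mu [rad], coefs, kappa)."""
        resid = self.theta - self._mean_angle(mu, np.asarray(coefs, dtype=float))
        # log I0 via the exponentially scaled Bessel for large-kappa stability
        log_i0 = np.log(special.i0e(kappa)) + kappa
        return float(-self.nobs * (np.log(2 * np.pi) + log_i0) + kappa * np.sum(np.cos(resid)))

    def _cos_sum(self, params: np.ndarray, free: np.ndarray) -> tuple[float, np.ndarray]:
        """sum cos(residual) and its gradient over (mu, coefs[free])."""
        mu = params[0]
        coefs = np.zeros(self.exog.shape[1])
        coefs[free] = params[1:]
        eta = self.exog @ coefs
        resid = self.theta - mu - 2.0 * np.arctan(eta)
        s = np.sin(resid)
        val = float(np.sum(np.cos(resid)))
        grad_mu = float(np.sum(s))
        grad_c = (s * 2.0 / (1.0 + eta**2)) @ self.exog[:, free]
        return val, np.concatenate(([grad_mu], grad_c))

    def fit(
        self,
        start_params: Sequence[float] | None = None,
        max_iter: int = 500,
        tol: float = 1e-10,
        extra_starts: bool = True,
    ) -> "CircularPhaseGLMResults":
        """Maximize the likelihood and return a results object.

        Multi-start: mu0 at the circular mean shifted by {0, +6, -6, 12} h
        with zero coefficients (the arctan link can make the cosine criterion
        multimodal), plus ``start_params`` (mu_ct, coefs...) if given; the
        best accepted optimum wins.  Accepted quasi-Newton steps never
        decrease the criterion; the history is kept on the results.
        """
        k = self.exog.shape[1]
        free = np.ptp(self.exog, axis=0) > 0
        unidentifiable = [n for n, f in zip(self.exog_names, free) if not f]

        z = np.exp(1j * self.theta).mean()
        mu_hat = float(np.angle(z))
        starts: list[np.ndarray] = []
        if start_params is not None:
            sp = np.asarray(start_params, dtype=float)
            starts.append(
                np.concatenate(([ct_to_radians(sp[0])], sp[1:][free]))
            )
        shifts_h = [0.0, 6.0, -6.0, 12.0] if extra_starts else [0.0]
        for dh in shifts_h:
            starts.append(
                np.concatenate(([mu_hat + dh * _RAD_PER_HOUR], np.zeros(int(free.sum()))))
            )

        best = None
        best_val = -np.inf
        best_hist: list[float] = []
        for x0 in starts:
            hist: list[float] = []

            def neg(params):
                val, grad = self._cos_sum(params, free)
                return -val, -grad

            def cb(params):
                hist.append(self._cos_sum(params, free)[0])

            res = optimize.minimize(
                neg,
                x0,
                jac=True,
                method="L-BFGS-B",
                callback=cb,
                options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12},
            )
            val = -res.fun
            if val > best_val:
                best_val = val
                best = res
                best_hist = [self._cos_sum(x0, free)[0]] + hist

        params = best.x
        mu = float(np.mod(params[0], 2 * np.pi))
        coefs = np.zeros(k)
        coefs[free] = params[1:]
        rbar = best_val / self.nobs
        kappa = vonmises_kappa_from_rbar(rbar)
        loglik = self.loglike(mu, coefs, kappa)
        converged = bool(best.success) and np.isfinite(loglik)

        bse = self._standard_errors(mu, coefs, kappa, free)
        return CircularPhaseGLMResults(
            model=self,
            mu_rad=mu,
            coefs=coefs,
            kappa=kappa,
            loglik=loglik,
            converged=converged,
            unidentifiable=tuple(unidentifiable),
            bse=bse,
            criterion_history=tuple(best_hist),
            n_iter=int(best.nit),
        )

    def _standard_errors(
        self, mu: float, coefs: np.ndarray, kappa: float, free: np.ndarray
    ) -> dict:
        """Observed-information SEs by central differences of the analytic
        score over the free parameters (mu, coefs[free], kappa)."""
        nf = int(free.sum())

        def score(p):
            mu_, kappa_ = p[0], p[-1]
            c_ = np.zeros_like(coefs)
            c_[free] = p[1:-1]
            eta = self.exog @ c_
            resid = self.theta - mu_ - 2.0 * np.arctan(eta)
            s = np.sin(resid)
            g = np.empty(nf + 2)
            g[0] = kappa_ * np.sum(s)
            g[1:-1] = kappa_ * ((s * 2.0 / (1.0 + eta**2)) @ self.exog[:, free])
            a = special.i1e(kappa_) / special.i0e(kappa_)
            g[-1] = -self.nobs * a + np.sum(np.cos(resid))
            return g

        p0 = np.concatenate(([mu], coefs[free], [kappa]))
        h = 1e-5 * np.maximum(np.abs(p0), 1.0)
        hess = np.empty((nf + 2, nf + 2))
        for j in range(nf + 2):
            dp = np.zeros_like(p0)
            dp[j] = h[j]
            hess[:, j] = (score(p0 + dp) - score(p0 - dp)) / (2 * h[j])
        hess = 0.5 * (hess + hess.T)
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate designs
            se = np.full(nf + 2, np.nan)
        out = {"mu_ct": se[0] / _RAD_PER_HOUR, "kappa": se[-1]}
        names = [n for n, f in zip(self.exog_names, free) if f]
        for n, s in zip(names, se[1:-1]):
            out[n] = s
        for n, f in zip(self.exog_names, free):
            if not f:
                out[n] = np.nan
        return out


@dataclass(frozen=True)
class CircularPhaseGLMResults:
    """Fitted (mu, c, kappa) with uncertainties and diagnostics."""

    model: CircularPhaseGLM
    mu_rad: float
    coefs: np.ndarray
    kappa: float
    loglik: float
    converged: bool
    unidentifiable: tuple[str, ...]
    bse: dict
    criterion_history: tuple[float, ...]
    n_iter: int

    @property
    def mu_ct(self) -> float:
        """Mean offset in CT hours."""
        return float(radians_to_ct(self.mu_rad))

    @property
    def params(self) -> dict:
        out = {"mu_ct": self.mu_ct}
        out.update(dict(zip(self.model.exog_names, self.coefs)))
        out["kappa"] = self.kappa
        return out

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def predict(self, exog) -> np.ndarray:
        """Predicted mean phase in CT hours for rows of regressor scores."""
        if isinstance(exog, pd.DataFrame):
            exog = exog[self.model.exog_names].to_numpy(dtype=float)
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        mean = self.mu_rad + 2.0 * np.arctan(exog @ self.coefs)
        return radians_to_ct(mean)

    def conf_int(self, alpha: float = 0.05) -> dict:
        """Wald intervals per parameter (mu interval in CT hours, unwrapped
        around the estimate)."""
        from scipy.stats import norm

        zq = norm.ppf(1 - alpha / 2)
        out = {}
        for name, est in self.params.items():
            se = self.bse.get(name, np.nan)
            out[name] = (est - zq * se, est + zq * se)
        return out

    def summary(self) -> str:
        lines = [
            "Circular phase regression (von Mises, 2*arctan link)",
            f"  observations: {self.nobs}    log-likelihood: {self.loglik:.4f}",
            f"  converged: {self.converged}    iterations: {self.n_iter}",
            "",
            f"  {'param':<10}{'estimate':>12}{'std err':>12}",
        ]
        for name, est in self.params.items():
            se = self.bse.get(name, np.nan)
            lines.append(f"  {name:<10}{est:>12.4f}{se:>12.4f}")
        if self.unidentifiable:
            lines.append(
                f"  (constant regressors fixed at 0: {', '.join(self.unidentifiable)})"
            )
        return "\n".join(lines)


def predict_phase(fit: CircularPhaseGLMResults, s_e: float, s_d: float, s_rre: float) -> float:
    """Mean peak phase (CT hours) for one triple of TF-group scores.

    wrap24(mu_CT + (24/2pi) * 2*arctan(c_E s_E + c_D s_D + c_RRE s_RRE)); the
    2*arctan term spans (-pi, pi) radians, i.e. (-12, +12) h around mu.
    """
    return float(fit.predict(np.array([[s_e, s_d, s_rre]]))[0])


# ---------------------------------------------------------------------------
# Circular summaries
# ---------------------------------------------------------------------------


def rayleigh_test(phases_ct: Iterable[float]) -> tuple[float, float, float]:
    """Rayleigh test of non-uniform mean direction.

    Returns (mean_direction_ct, resultant_length, p_value) with
    Z = n * Rbar^2 and the second-order tail approximation
    p = exp(-Z) * (1 + (2Z - Z^2) / (4n)), clipped to [0, 1].
    """
    phases = np.asarray(list(phases_ct), dtype=float)
    n = phases.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least 2 phases")
    z = np.exp(1j * ct_to_radians(phases)).mean()
    rbar = float(np.abs(z))
    zstat = n * rbar**2
    p = float(np.exp(-zstat) * (1.0 + (2 * zstat - zstat**2) / (4 * n)))
    return float(radians_to_ct(np.angle(z))), rbar, float(np.clip(p, 0.0, 1.0))


def circular_median_ct(phases_ct: Iterable[float]) -> float:
    """Circular median: the observed phase minimizing mean absolute circular
    deviation; ties broken by the smaller CT value."""
    phases = np.asarray(list(phases_ct), dtype=float)
    if phases.size == 0:
        raise ValueError("empty phase list")
    diffs = np.abs(phases[:, None] - phases[None, :])
    circ = np.minimum(diffs, HOURS_PER_CYCLE - diffs)
    mean_dev = circ.mean(axis=1)
    order = np.lexsort((phases, mean_dev))  # smallest deviation, then smallest CT
    return float(phases[order[0]])


def tf_combo_summary(
    hits: HitMatrix, registry: Registry, observations: pd.DataFrame
) -> pd.DataFrame:
    """Pooled-phase summary per TF-binding combination.

    Each gene is labeled by the set of TF groups with at least one ChIP-seq
    hit (any E-box dataset, the D-box dataset, any RRE dataset); genes with
    no group hit form the "none" class.  Per combo: number of pooled
    observations, circular median phase (CT) and the Rayleigh p-value.
    """
    if hits.dataset_ids != registry.dataset_ids:
        raise ValueError("hit matrix columns do not match registry order")
    present = {}
    for name in TF_GROUP_NAMES:
        mask = registry.group_mask(name)
        present[name] = hits.values[:, mask].any(axis=1)
    labels = []
    for g in range(hits.n_genes):
        groups = [name for name in TF_GROUP_NAMES if present[name][g]]
        labels.append("+".join(groups) if groups else "none")
    combo_of_gene = pd.Series(labels, index=pd.Index(hits.gene_ids, name="gene_id"))

    obs = observations.copy()
    obs["combo"] = obs["gene_id"].map(combo_of_gene)
    obs = obs.dropna(subset=["combo"])
    rows = []
    for combo, grp in obs.groupby("combo"):
        phases = grp["phase_ct"].to_numpy(dtype=float)
        if phases.size >= 2:
            _, _, p = rayleigh_test(phases)
        else:
            p = np.nan
        rows.append(
            {
                "combo": combo,
                "n": int(phases.size),
                "median_phase_ct": circular_median_ct(phases) if phases.size else np.nan,
                "rayleigh_p": p,
            }
        )
    return pd.DataFrame(rows).sort_values("combo").reset_index(drop=True)
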