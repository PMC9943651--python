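"""1:1 protein-oligonucleotide binding with a noncompetitive nonspecific term.

Model
-----
A labelled oligonucleotide (the "probe", total concentration ``R`` μM) is
titrated with protein (total ``P`` μM).  A fraction ``NS`` of the protein is
sequestered in a nonspecific complex that does not compete with specific
binding, so the protein available for the specific 1:1 complex is
``P' = P(1-NS)``.  Mass action with dissociation constant ``K_D`` gives the
quadratic

    K_D * x = (P' - x) * (R - x)

whose physical ("minus") root is the specific complex concentration
``x = Prot_RNA``.  The measured anisotropy is

    A = A0 + dA * (x + NS * P) / R

i.e. the nonspecific complex contributes to the anisotropy signal with the
same amplitude as the specific one.  Note the NS term grows linearly in P
without saturating; at high protein it dominates unless NS is small.  The
model is implemented exactly in this form.

Replicate titrations of one condition are fitted globally with shared
(K_D, A0, dA, NS).  NS > 0 is tested against NS = 0 by the least-squares
AIC, ``n·ln(RSS/n) + 2k`` with k counting free parameters plus the noise
scale; ties go to the simpler NS = 0 model.  Outliers are flagged once by
|studentized residual| > 3 against a robust (MAD-based) noise scale and the
fit repeated on the reduced set (single pass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .structio import TitrationSeries

OUTLIER_Z = 3.0
MAX_OUTLIER_FRACTION = 0.2
N_MULTISTART = 5


@dataclass
class BindingParams:
    """Shared parameters of the 1:1 + NS anisotropy model.

    k_d in μM; a0 (baseline) and da (anisotropy change on binding, ΔA)
    dimensionless; ns a fraction in [0, 1).
    """

    k_d: float
    a0: float
    da: float
    ns: float = 0.0

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise ValueError("K_D must be positive")
        if not 0.0 <= self.ns < 1.0:
            raise ValueError("NS must lie in [0, 1)")
        if not np.isfinite(self.da):
            raise ValueError("dA must be finite")


@dataclass
class SpeciesState:
    """Equilibrium species concentrations (μM) at one titration point."""

    prot_total: float
    rna_total: float
    prot_rna: float
    ns: float = 0.0

    @property
    def ns_complex(self) -> float:
        return self.ns * self.prot_total

    @property
    def rna_free(self) -> float:
        return self.rna_total - self.prot_rna

    @property
    def prot_free(self) -> float:
        return self.prot_total * (1.0 - self.ns) - self.prot_rna


@dataclass
class BindingFit:
    """Result of a global fit over replicate titrations."""

    params: BindingParams
    std_errors: dict[str, float]
    rss: float
    n_points: int
    aic: float
    ns_model: bool
    outlier_mask: np.ndarray
    converged: bool
    probe_conc: float = 0.0
    condition: str = ""
    oligo: str = ""
    n_free: int = 0

    def __post_init__(self) -> None:
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if self.rss < 0:
            raise ValueError("RSS cannot be negative")


def bound_complex(prot_total, rna_total, k_d, ns=0.0):
    """Specific complex concentration Prot_RNA (μM).

    Solves K_D·x = (P'-x)(R-x) with P' = prot_total·(1-ns) for the physical
    (minus) root, written in the cancellation-free form
    x = 2·P'·R / (b + sqrt(b² - 4·P'·R)) with b = P' + R + K_D.
    Vectorised over prot_total.
    """
    p = np.asarray(prot_total, dtype=float)
    if np.any(p < 0):
        raise ValueError("prot_total must be non-negative")
    if rna_total <= 0:
        raise ValueError("rna_total must be positive")
    if k_d < 0:
        raise ValueError("k_d must be non-negative")
    if not 0.0 <= ns < 1.0:
        raise ValueError("ns must lie in [0, 1)")
    pp = p * (1.0 - ns)
    r = float(rna_total)
    b = pp + r + k_d
    disc = b * b - 4.0 * pp * r
    disc = np.maximum(disc, 0.0)
    denom = b + np.sqrt(disc)
    x = np.where(denom > 0, 2.0 * pp * r / np.where(denom > 0, denom, 1.0), 0.0)
    x = np.clip(x, 0.0, np.minimum(pp, r))
    return x if x.ndim else float(x)


def species_state(prot_total: float, rna_total: float, k_d: float, ns: float = 0.0) -> SpeciesState:
    """Full species breakdown at one point (convenience wrapper)."""
    x = bound_complex(prot_total, rna_total, k_d, ns)
    return SpeciesState(prot_total=prot_total, rna_total=rna_total, prot_rna=float(x), ns=ns)


def predict_anisotropy(params: BindingParams, prot_total, rna_total: float):
    """Model anisotropy A0 + dA·(Prot_RNA + NS·Prot_total)/RNA_total."""
    if rna_total <= 0:
        raise ValueError("rna_total must be positive")
    x = bound_complex(prot_total, rna_total, params.k_d, params.ns)
    p = np.asarray(prot_total, dtype=float)
    return params.a0 + params.da * (x + params.ns * p) / rna_total


def simulate_titration(
    params: BindingParams,
    probe_conc: float = 0.05,
    protein_grid=None,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "",
    oligo: str = "",
) -> list[TitrationSeries]:
    """Simulate replicate titrations with additive homoscedastic Gaussian noise.

    Defaults mirror the experimental design the model was built for: 50 nM
    probe, triplicate, protein spanning 0.1-120 μM (12 log-spaced points).
    """
    if protein_grid is None:
        protein_grid = default_protein_grid()
    protein_grid = np.asarray(protein_grid, dtype=float)
    if protein_grid.size == 0:
        raise ValueError("protein grid must not be empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    mean = predict_anisotropy(params, protein_grid, probe_conc)
    out = []
    for rep in range(n_replicates):
        noise = rng.normal(0.0, noise_sd, size=protein_grid.shape) if noise_sd > 0 else 0.0
        out.append(
            TitrationSeries(
                probe_conc=probe_conc,
                protein_conc=protein_grid.copy(),
                anisotropy=mean + noise,
                condition=condition,
                replicate_id=rep + 1,
                oligo=oligo,
            )
        )
    return out


def default_protein_grid(n_points: int = 12, lo: float = 0.1, hi: float = 120.0) -> np.ndarray:
    """Log-spaced protein grid over the standard titration range (μM)."""
    return np.geomspace(lo, hi, n_points)


# ---------------------------------------------------------------------------
# fitting


def _stack(series: list[TitrationSeries]):
    probe = series[0].probe_conc
    for s in series[1:]:
        if abs(s.probe_conc - probe) > 1e-12:
            raise ValueError("all series in a global fit must share probe_conc")
    p = np.concatenate([s.protein_conc for s in series])
    a = np.concatenate([s.anisotropy for s in series])
    return probe, p, a


def _residuals(theta, p, a, probe, ns_free):
    k_d, a0, da = theta[0], theta[1], theta[2]
    ns = theta[3] if ns_free else 0.0
    x = bound_complex(p, probe, max(k_d, 1e-12), min(max(ns, 0.0), 1 - 1e-9))
    model = a0 + da * (x + ns * p) / probe
    return model - a


def fit_global(
    series: list[TitrationSeries],
    ns_free: bool = True,
    outlier_mask: np.ndarray | None = None,
) -> BindingFit:
    """Global least-squares fit of replicate titrations.

    All series share (K_D, A0, dA) and, when ``ns_free``, NS; otherwise NS is
    fixed at 0.  Starting values: A0 = min(anisotropy), dA = range,
    K_D = protein concentration nearest the half-range anisotropy, NS = 0.01;
    five multistart perturbations guard against local minima.  Standard
    errors come from the Gauss-Newton covariance at the optimum.  Points with
    ``outlier_mask`` True are excluded from the fit but retained in the mask
    bookkeeping.
    """
    if not series:
        raise ValueError("need at least one titration series")
    for s in series:
        if len(s) < 4:
            raise ValueError("each series needs at least 4 points")
    probe, p_all, a_all = _stack(series)
    if outlier_mask is None:
        outlier_mask = np.zeros(p_all.shape, dtype=bool)
    outlier_mask = np.asarray(outlier_mask, dtype=bool)
    if outlier_mask.shape != p_all.shape:
        raise ValueError("outlier_mask length mismatch")
    keep = ~outlier_mask
    p, a = p_all[keep], a_all[keep]
    n = p.size

    a0_init = float(np.min(a))
    da_init = float(np.ptp(a)) or 1e-3
    half = a0_init + 0.5 * da_init
    kd_init = float(p[np.argmin(np.abs(a - half))]) or 1.0
    kd_init = max(kd_init, 1e-3)
    theta0 = [kd_init, a0_init, da_init] + ([0.01] if ns_free else [])
    lb = [1e-6, -np.inf, -np.inf] + ([0.0] if ns_free else [])
    ub = [1e6, np.inf, np.inf] + ([1 - 1e-6] if ns_free else [])

    rng = np.random.default_rng(12345)
    starts = [np.array(theta0, dtype=float)]
    for _ in range(N_MULTISTART - 1):
        t = np.array(theta0, dtype=float)
        t[0] *= np.exp(rng.normal(0, 1.0))  # K_D on log scale
        t[2] *= np.exp(rng.normal(0, 0.3))
        if ns_free:
            t[3] = min(max(abs(rng.normal(0.01, 0.02)), 0.0), 0.5)
        starts.append(np.clip(t, lb, ub))

    best = None
    for t0 in starts:
        try:
            res = least_squares(
                _residuals,
                t0,
                bounds=(lb, ub),
                args=(p, a, probe, ns_free),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    k_free = 3 + (1 if ns_free else 0)
    if best is None:
        params = BindingParams(k_d=kd_init, a0=a0_init, da=da_init, ns=0.0)
        return BindingFit(
            params=params,
            std_errors={},
            rss=float(np.sum(_residuals(np.array(theta0), p, a, probe, ns_free) ** 2)),
            n_points=n,
            aic=np.inf,
            ns_model=ns_free,
            outlier_mask=outlier_mask,
            converged=False,
            probe_conc=probe,
            condition=series[0].condition,
            oligo=series[0].oligo,
            n_free=k_free,
        )

    theta = best.x
    rss = float(2 * best.cost)
    aic = _aic(rss, n, k_free)
    names = ["k_d", "a0", "da"] + (["ns"] if ns_free else [])
    std_errors = _gauss_newton_se(best.jac, rss, n, k_free, names)
    params = BindingParams(
        k_d=float(theta[0]),
        a0=float(theta[1]),
        da=float(theta[2]),
        ns=float(theta[3]) if ns_free else 0.0,
    )
    # an honest convergence flag: optimizer reported success and the
    # amplitude is resolved relative to its own uncertainty
    converged = bool(best.status > 0)
    da_se = std_errors.get("da", np.inf)
    if not np.isfinite(da_se) or (da_se > 0 and abs(params.da) < 2.0 * da_se):
        converged = False
    return BindingFit(
        params=params,
        std_errors=std_errors,
        rss=rss,
        n_points=n,
        aic=aic,
        ns_model=ns_free,
        outlier_mask=outlier_mask,
        converged=converged,
        probe_conc=probe,
        condition=series[0].condition,
        oligo=series[0].oligo,
        n_free=k_free,
    )


def _aic(rss: float, n: int, k_free: int) -> float:
    """Least-squares AIC, n·ln(RSS/n) + 2k, with k = k_free + 1 (noise scale)."""
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * (k_free + 1)


def _gauss_newton_se(jac, rss, n, k, names):
    dof = max(n - k, 1)
    s2 = rss / dof
    try:
        jtj = jac.T @ jac
        cov = s2 * np.linalg.pinv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(names), np.inf)
    return dict(zip(names, se))


def select_model(fit_ns: BindingFit, fit_no_ns: BindingFit):
    """Choose between the NS-free and NS=0 fits by AIC (lower wins, ties to
    the simpler NS=0 model).  Returns (chosen_fit, decision_record)."""
    if fit_ns.n_points != fit_no_ns.n_points or not np.array_equal(
        fit_ns.outlier_mask, fit_no_ns.outlier_mask
    ):
        raise ValueError("model selection requires fits on identical point sets")
    ns_wins = fit_ns.aic < fit_no_ns.aic
    chosen = fit_ns if ns_wins else fit_no_ns
    record = {
        "aic_ns": fit_ns.aic,
        "aic_no_ns": fit_no_ns.aic,
        "delta_aic": fit_ns.aic - fit_no_ns.aic,
        "selected": "NS>0" if ns_wins else "NS=0",
    }
    return chosen, record


def flag_outliers(fit: BindingFit, series: list[TitrationSeries]) -> np.ndarray:
    """Flag points with |internally studentized residual| > 3.

    Studentization divides by a robust scale (1.4826·MAD of the residuals)
    with the leverage correction from the Gauss-Newton hat matrix at the
    fitted optimum; the robust scale keeps gross contamination from masking
    itself by inflating the noise estimate.  If more than 20% of points
    would be flagged the model is deemed misfit and a ValueError is raised
    instead.
    """
    probe, p, a = _stack(series)
    theta = [fit.params.k_d, fit.params.a0, fit.params.da]
    if fit.ns_model:
        theta.append(fit.params.ns)
    theta = np.asarray(theta, dtype=float)
    r = _residuals(theta, p, a, probe, fit.ns_model)
    # numerical jacobian for leverage
    jac = np.empty((p.size, theta.size))
    for j in range(theta.size):
        h = 1e-6 * max(abs(theta[j]), 1e-6)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        jac[:, j] = (
            _residuals(tp, p, a, probe, fit.ns_model)
            - _residuals(tm, p, a, probe, fit.ns_model)
        ) / (2 * h)
    n, k = p.size, theta.size
    s = 1.4826 * np.median(np.abs(r - np.median(r)))
    if s < 1e-10:  # effectively noiseless fit; nothing to flag
        return np.zeros(n, dtype=bool)
    try:
        hat = np.einsum("ij,jk,ik->i", jac, np.linalg.pinv(jac.T @ jac), jac)
    except np.linalg.LinAlgError:
        hat = np.zeros(n)
    hat = np.clip(hat, 0.0, 1.0 - 1e-9)
    t = r / (s * np.sqrt(1.0 - hat))
    mask = np.abs(t) > OUTLIER_Z
    if mask.mean() > MAX_OUTLIER_FRACTION:
        raise ValueError(
            f"{mask.sum()}/{n} points exceed the outlier threshold; "
            "this signals model misfit, not outliers — refusing to flag"
        )
    return mask


def fit_with_model_selection(series: list[TitrationSeries], ns: str = "auto"):
    """Full analysis of one condition: preliminary fit, one outlier pass,
    refit of both NS models, AIC selection.

    ``ns`` is "auto" (AIC decides), "on" (NS free) or "off" (NS = 0).
    Returns (chosen_fit, decision_record).
    """
    if ns not in ("auto", "on", "off"):
        raise ValueError("ns must be auto, on or off")
    prelim = fit_global(series, ns_free=(ns != "off"))
    mask = (
        flag_outliers(prelim, series)
        if prelim.converged
        else np.zeros(prelim.n_points, dtype=bool)
    )
    if ns == "auto":
        fit_ns = fit_global(series, ns_free=True, outlier_mask=mask)
        fit_no = fit_global(series, ns_free=False, outlier_mask=mask)
        chosen, record = select_model(fit_ns, fit_no)
    else:
        chosen = fit_global(series, ns_free=(ns == "on"), outlier_mask=mask)
        record = {"selected": "NS>0" if ns == "on" else "NS=0", "forced": True}
    record["n_outliers"] = int(mask.sum())
    record["outlier_indices"] = np.flatnonzero(mask).tolist()
    return chosen, record
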