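"""Non-compartmental analysis, compartmental fitting and model validation.

NCA follows standard practice: Cmax/Tmax by direct maximum, AUC0-t by the
linear-up/log-down trapezoid, and AUC0-inf by adding Clast/λz with λz from
a log-linear regression over the best adjusted-R² terminal window of at
least three points (ties broken toward the longer window).  Validation
uses the percent prediction error 100·(pred − obs)/obs with a strict
|%PE| < 25 acceptance rule on AUC0-t and Cmax, and the log10 fold-error
aggregates AFE/AAFE alongside MAE and RMSE.

Compartmental fits are weighted (proportional-error) least squares of
1-, 2- or 3-compartment first-order-absorption oral models via lmfit with
seeded multi-start initialisation; AIC supports model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "ObservedProfile",
    "PKSummary",
    "CompartmentalFit",
    "ValidationReport",
    "nca_summary",
    "percent_prediction_error",
    "aggregate_metrics",
    "acceptance_check",
    "fit_compartmental",
    "oral_compartment_curve",
]

PE_ACCEPTANCE_LIMIT = 25.0  # %, strict


class FitError(RuntimeError):
    """Compartmental fit failed to converge from every start."""


@dataclass(frozen=True)
class ObservedProfile:
    times: tuple[float, ...]  # h
    concentrations: tuple[float, ...]  # µg/mL
    dose: float  # mg
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.times) < 4:
            raise ValueError("a profile needs at least 4 points")
        if list(self.times) != sorted(self.times):
            raise ValueError("times must be ascending")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")
        if len(self.times) != len(self.concentrations):
            raise ValueError("times and concentrations differ in length")

    @classmethod
    def read(cls, path) -> "ObservedProfile":
        """Read the delimited-text profile format (header line:
        ``# dose_mg=<d> label=<text>``; columns time_h, conc_ug_per_mL)."""
        dose, label = 0.0, ""
        times, concs = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if tok.startswith("dose_mg="):
                            dose = float(tok.split("=", 1)[1])
                        elif tok.startswith("label="):
                            label = tok.split("=", 1)[1]
                    continue
                if line.startswith("time"):
                    continue
                t, c = line.split("\t")
                times.append(float(t))
                concs.append(float(c))
        return cls(tuple(times), tuple(concs), dose, label)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# dose_mg={self.dose:g} label={self.label}\n")
            fh.write("time_h\tconc_ug_per_mL\n")
            for t, c in zip(self.times, self.concentrations):
                fh.write(f"{t:.6g}\t{c:.8g}\n")


@dataclass(frozen=True)
class PKSummary:
    cmax: float  # µg/mL
    tmax: float  # h
    auc_0_t: float  # µg·h/mL
    auc_0_inf: float | None  # µg·h/mL, None when λz is not identifiable
    lambda_z: float | None = None  # 1/h
    cl_over_f: float | None = None  # L/h
    cmax_liver: float | None = None
    f_percent: float | None = None
    fa_percent: float | None = None
    fdp_percent: float | None = None
    vd_per_kg: float | None = None

    def __post_init__(self) -> None:
        if self.auc_0_inf is not None and self.auc_0_inf < self.auc_0_t - 1e-9:
            raise ValueError("AUC0-inf cannot be below AUC0-t")


@dataclass(frozen=True)
class CompartmentalFit:
    n_compartments: int
    ka: float  # 1/h
    cl_f: float  # L/h
    vc_f: float  # L
    peripheral: tuple[tuple[float, float], ...]  # (Q L/h, V L) per peripheral
    objective: float  # weighted SSR
    aic: float

    def __post_init__(self) -> None:
        if min(self.ka, self.cl_f, self.vc_f) <= 0:
            raise ValueError("rate constants and volumes must be positive")


@dataclass
class ValidationReport:
    rows: list[dict] = field(default_factory=list)  # quantity, predicted, observed, percent_pe
    aggregates: dict[str, dict[str, float]] = field(default_factory=dict)

    def add(self, quantity: str, predicted: float, observed: float) -> None:
        self.rows.append({"quantity": quantity, "predicted": predicted,
                          "observed": observed,
                          "percent_pe": percent_prediction_error(predicted, observed)})

    def aggregate(self) -> None:
        quantities = {r["quantity"] for r in self.rows}
        for q in sorted(quantities):
            pairs = [(r["predicted"], r["observed"]) for r in self.rows
                     if r["quantity"] == q]
            afe, aafe, mae, rmse = aggregate_metrics(pairs)
            self.aggregates[q] = {"afe": afe, "aafe": aafe, "mae": mae, "rmse": rmse}

    @property
    def accepted(self) -> bool:
        return acceptance_check(self)


# ---------------------------------------------------------------------------
# NCA

def _auc_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    dt = np.diff(t)
    c0, c1 = c[:-1], c[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_down = (c0 - c1) / np.log(c0 / c1)
    linear = (c0 + c1) / 2.0
    use_log = (c1 < c0) & (c1 > 0)
    seg = np.where(use_log, log_down, linear)
    return float(np.sum(seg * dt))


def _terminal_lambda_z(t: np.ndarray, c: np.ndarray) -> tuple[float | None, int]:
    """λz from the best adjusted-R² window of >= 3 positive, post-peak
    points ending at tlast; ties go to the longer window."""
    pos = c > 0
    if pos.sum() < 3:
        return None, 0
    i_max = int(np.argmax(c))
    idx = np.nonzero(pos)[0]
    idx = idx[idx > i_max]
    if len(idx) < 3:
        return None, 0
    tt, lc = t[idx], np.log(c[idx])
    n = len(tt)
    # suffix regressions of ln C on t via reversed prefix sums
    def rev_cumsum(x):
        return np.cumsum(x[::-1])[::-1]
    sw = rev_cumsum(np.ones(n))
    st = rev_cumsum(tt)
    sy = rev_cumsum(lc)
    stt = rev_cumsum(tt * tt)
    sty = rev_cumsum(tt * lc)
    syy = rev_cumsum(lc * lc)
    m = sw
    denom = m * stt - st ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (m * sty - st * sy) / denom
        ss_tot = syy - sy ** 2 / m
        ss_res = ss_tot - slope * (sty - st * sy / m)
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
    valid = (m >= 3) & (slope < 0) & np.isfinite(adj)
    if not valid.any():
        return None, 0
    adj = np.where(valid, adj, -np.inf)
    # earliest start index among ties -> the longer window wins
    candidates = np.nonzero(adj >= adj.max() - 1e-10)[0]
    best = int(candidates.min())
    return float(-slope[best]), int(m[best])


def nca_summary(times, concentrations, dose: float) -> PKSummary:
    """Non-compartmental summary of a concentration-time profile.

    ``dose`` in mg; CL/F = dose/AUC0-inf comes out in L/h directly for
    µg·h/mL AUC values.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or t.shape != c.shape or len(t) < 4:
        raise ValueError("need matching 1-d arrays of >= 4 points")
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_t = _auc_lin_up_log_down(t, c)
    lambda_z, _n_used = _terminal_lambda_z(t, c)
    auc_inf = cl_f = None
    if lambda_z is not None:
        c_last = float(c[c > 0][-1])
        auc_inf = auc_t + c_last / lambda_z
        if dose > 0:
            cl_f = dose / auc_inf
    return PKSummary(cmax=cmax, tmax=tmax, auc_0_t=auc_t, auc_0_inf=auc_inf,
                     lambda_z=lambda_z, cl_over_f=cl_f)


# ---------------------------------------------------------------------------
# validation metrics

def percent_prediction_error(pred: float, obs: float) -> float:
    """%PE = 100 (pred - obs) / obs."""
    if obs == 0:
        raise ValueError("observed value must be nonzero")
    return 100.0 * (pred - obs) / obs


def aggregate_metrics(pairs) -> tuple[float, float, float, float]:
    """(AFE, AAFE, MAE, RMSE) over (pred, obs) pairs.

    AFE = 10^mean(log10 pred/obs), AAFE = 10^mean|log10 pred/obs|.
    """
    pred = np.array([p for p, _ in pairs], dtype=float)
    obs = np.array([o for _, o in pairs], dtype=float)
    if len(pred) == 0:
        raise ValueError("no pairs")
    if (pred <= 0).any() or (obs <= 0).any():
        raise ValueError("fold-error metrics require positive values")
    logs = np.log10(pred / obs)
    afe = float(10.0 ** logs.mean())
    aafe = float(10.0 ** np.abs(logs).mean())
    mae = float(np.abs(pred - obs).mean())
    rmse = float(np.sqrt(((pred - obs) ** 2).mean()))
    return afe, aafe, mae, rmse


def acceptance_check(report: ValidationReport) -> bool:
    """Strict rule: every AUC0-t and Cmax |%PE| < 25."""
    relevant = [r for r in report.rows
                if r["quantity"].lower().startswith(("auc", "cmax"))]
    if not relevant:
        raise ValueError("report holds no AUC/Cmax rows")
    return all(abs(r["percent_pe"]) < PE_ACCEPTANCE_LIMIT for r in relevant)


# ---------------------------------------------------------------------------
# compartmental models

def oral_compartment_curve(t, dose: float, ka: float, cl_f: float, vc_f: float,
                           peripheral=()) -> np.ndarray:
    """Plasma concentration (µg/mL) of an n-compartment first-order oral
    model; dose mg, ka 1/h, CL/F L/h, Vc/F L, peripheral (Q L/h, V L).

    Solved by eigendecomposition of the (depot + compartments) linear
    system, valid for 1-3 compartments.
    """
    t = np.asarray(t, dtype=float)
    n_per = len(peripheral)
    dim = 2 + n_per  # depot, central, peripherals
    a_mat = np.zeros((dim, dim))
    a_mat[0, 0] = -ka
    a_mat[1, 0] = ka
    a_mat[1, 1] = -cl_f / vc_f
    for i, (q, v) in enumerate(peripheral):
        j = 2 + i
        a_mat[1, 1] -= q / vc_f
        a_mat[1, j] = q / v
        a_mat[j, 1] = q / vc_f
        a_mat[j, j] = -q / v
    w, vecs = np.linalg.eig(a_mat)
    y0 = np.zeros(dim)
    y0[0] = dose * 1000.0  # µg
    coef = np.linalg.solve(vecs, y0)
    amounts = (vecs[1, :] * coef) @ np.exp(np.outer(w, t))
    return np.real(amounts) / (vc_f * 1000.0)  # µg / mL


def fit_compartmental(profile: ObservedProfile, n: int = 1, n_starts: int = 5,
                      seed: int = 0) -> CompartmentalFit:
    """Weighted least-squares fit of an oral n-compartment model.

    Proportional-error weighting (1/obs), multi-start initialisation from
    NCA-derived heuristics; raises :class:`FitError` if no start converges.
    """
    if n not in (1, 2, 3):
        raise ValueError("n must be 1, 2 or 3")
    t = np.array(profile.times)
    c = np.array(profile.concentrations)
    # log residuals when all observations are positive (the natural scale
    # for proportional, log-normal error); 1/obs weighting otherwise
    log_scale = bool(np.all(c > 0))
    weights = 1.0 / np.maximum(c, max(c.max() * 1e-3, 1e-12))

    # heuristics from the data
    s = nca_summary(t, c, profile.dose)
    auc_guess = s.auc_0_inf or s.auc_0_t
    cl0 = profile.dose / auc_guess if auc_guess > 0 else 1.0
    v0 = profile.dose * 1000.0 / (c.max() * 1000.0) if c.max() > 0 else 50.0
    ka0 = max(1.0 / max(s.tmax, 0.1), 0.3)

    def residuals(params):
        peripheral = [(params[f"q{i}"].value, params[f"v{i}"].value)
                      for i in range(2, n + 1)]
        model = oral_compartment_curve(t, profile.dose, params["ka"].value,
                                       params["cl"].value, params["vc"].value,
                                       peripheral)
        if log_scale:
            return np.log(np.maximum(model, 1e-12)) - np.log(c)
        return (model - c) * weights

    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        factor = 1.0 if start == 0 else float(np.exp(rng.normal(0, 0.7)))
        params = lmfit.Parameters()
        params.add("ka", value=ka0 * factor, min=1e-3, max=50.0)
        params.add("cl", value=cl0 / factor, min=1e-4, max=1e3)
        params.add("vc", value=v0 * (factor if start % 2 else 1 / factor),
                   min=1e-2, max=5e3)
        for i in range(2, n + 1):
            params.add(f"q{i}", value=cl0 * (0.5 * i) * factor, min=1e-4, max=1e3)
            params.add(f"v{i}", value=v0 * i * factor, min=1e-2, max=5e3)
        try:
            res = lmfit.minimize(residuals, params, method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitError(f"no convergence for the {n}-compartment model "
                       f"after {n_starts} starts")
    p = best.params
    peripheral = tuple((p[f"q{i}"].value, p[f"v{i}"].value) for i in range(2, n + 1))
    return CompartmentalFit(n_compartments=n, ka=p["ka"].value, cl_f=p["cl"].value,
                            vc_f=p["vc"].value, peripheral=peripheral,
                            objective=float(best.chisqr), aic=float(best.aic))


def select_compartments(profile: ObservedProfile, candidates=(1, 2),
                        seed: int = 0) -> CompartmentalFit:
    """Fit each candidate model and keep the lowest-AIC one."""
    fits = [fit_compartmental(profile, n, seed=seed) for n in candidates]
    return min(fits, key=lambda f: f.aic)
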