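"""Reporter-gene plate analysis for a CRE-luciferase receptor-activation assay.

Raw wells carry luminescence (RLU, reporter output) and fluorescence (RFU,
EGFP signal proportional to transfected cell mass).  Normalization divides RLU
by RFU (nRLU), expresses activity per experiment as fold over the vehicle
control and as percent of the positive control (set to 100%), and aggregates
as mean ± SEM over independent experiments.  Reduced RFU flags cytotoxicity
(one-way ANOVA + Bonferroni-corrected comparisons against vehicle).
Concentration–response data are fit with the four-parameter logistic
(variable-slope sigmoid)

    y = bottom + (top − bottom) / (1 + 10^((log10 EC50 − log10 c) · h)).

The plate schema is a tidy table with columns
``experiment, condition, compound_id, conc_uM, replicate, rlu, rfu`` and
condition labels ``vehicle``, ``positive`` or ``compound``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

PLATE_COLUMNS = ["experiment", "condition", "compound_id", "conc_uM", "replicate", "rlu", "rfu"]

#: Activity-call thresholds (% of positive control).
ACTIVE_THRESHOLD = 50.0
WEAK_THRESHOLD = 15.0


def _check_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    if (plate["rlu"] < 0).any() or (plate["rfu"] < 0).any():
        raise ValueError("RLU and RFU must be >= 0")
    return plate


def normalize_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-well normalized activity.

    Within each experiment: ``nrlu = rlu / rfu``; ``fold = nrlu / mean(vehicle
    nrlu)``; ``percent = 100·(nrlu − vehicle) / (positive − vehicle)``.  Wells
    with RFU = 0 are excluded with a warning; an experiment without vehicle or
    positive-control wells is fatal.
    """
    plate = _check_plate(plate).copy()
    zero = plate["rfu"] == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} wells with RFU = 0", stacklevel=2)
        plate = plate[~zero].copy()
    plate["nrlu"] = plate["rlu"] / plate["rfu"]

    out = []
    for exp, grp in plate.groupby("experiment"):
        veh = grp.loc[grp["condition"] == "vehicle", "nrlu"]
        pos = grp.loc[grp["condition"] == "positive", "nrlu"]
        if veh.empty or pos.empty:
            raise ValueError(f"experiment {exp!r} lacks vehicle or positive-control wells")
        v, p = veh.mean(), pos.mean()
        if p == v:
            raise ValueError(f"experiment {exp!r}: positive control equals vehicle")
        g = grp.copy()
        g["fold"] = g["nrlu"] / v
        g["percent"] = 100.0 * (g["nrlu"] - v) / (p - v)
        out.append(g)
    return pd.concat(out, ignore_index=True)


def aggregate_activity(normalized: pd.DataFrame) -> pd.DataFrame:
    """Aggregate normalized wells per compound and concentration: replicate
    means within experiments, then mean ± SEM across experiments."""
    comp = normalized[normalized["condition"] == "compound"]
    per_exp = (comp.groupby(["compound_id", "conc_uM", "experiment"])[["fold", "percent"]]
               .mean().reset_index())
    agg = per_exp.groupby(["compound_id", "conc_uM"]).agg(
        fold_mean=("fold", "mean"), fold_sem=("fold", "sem"),
        pct_mean=("percent", "mean"), pct_sem=("percent", "sem"),
        n_experiments=("experiment", "nunique"),
    ).reset_index()
    return agg


def flag_cytotoxicity(plate: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag compound/concentration groups whose EGFP fluorescence is
    significantly below vehicle.

    One-way ANOVA across all conditions on RFU, followed by Bonferroni-
    corrected two-sample comparisons of each compound group against vehicle;
    a group is cytotoxic iff its mean RFU is lower and the corrected p-value
    is below ``alpha``.  Groups with fewer than 3 replicates are marked
    ``insufficient data``.
    """
    plate = _check_plate(plate)
    veh = plate.loc[plate["condition"] == "vehicle", "rfu"].to_numpy()
    if len(veh) < 3:
        raise ValueError("need >= 3 vehicle replicates")
    groups = [(cid, conc, g["rfu"].to_numpy())
              for (cid, conc), g in plate[plate["condition"] == "compound"]
              .groupby(["compound_id", "conc_uM"])]
    rows = []
    testable = [(cid, conc, arr) for cid, conc, arr in groups if len(arr) >= 3]
    anova_p = 1.0
    if testable:
        arrays = [veh] + [arr for _, _, arr in testable]
        if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
            anova_p = 1.0  # identical constant signal everywhere
        else:
            anova_p = float(stats.f_oneway(*arrays).pvalue)
    m = max(len(testable), 1)
    for cid, conc, arr in groups:
        if len(arr) < 3:
            rows.append({"compound_id": cid, "conc_uM": conc, "cytotoxic": False,
                         "note": "insufficient data"})
            continue
        if anova_p >= alpha:
            rows.append({"compound_id": cid, "conc_uM": conc, "cytotoxic": False, "note": ""})
            continue
        t = stats.ttest_ind(arr, veh, equal_var=False)
        p_adj = min(1.0, float(t.pvalue) * m)
        toxic = bool(arr.mean() < veh.mean() and p_adj < alpha)
        rows.append({"compound_id": cid, "conc_uM": conc, "cytotoxic": toxic, "note": ""})
    return pd.DataFrame(rows, columns=["compound_id", "conc_uM", "cytotoxic", "note"])


@dataclass(frozen=True)
class ActivityCall:
    compound_id: str
    call: str  # active | weak | inactive | not_evaluable_cytotoxic


def classify_activity(compound_id: str, percent_low: float | None, percent_high: float | None,
                      cytotoxic_low: bool = False, cytotoxic_high: bool = False) -> ActivityCall:
    """Classify a compound from its percent activation at the two screening
    concentrations (typically 5 and 20 µM).

    Cytotoxic at both -> not evaluable; >= 50% at either evaluable
    concentration -> active; >= 15% -> weak; else inactive.
    """
    if cytotoxic_low and cytotoxic_high:
        return ActivityCall(compound_id, "not_evaluable_cytotoxic")
    vals = [v for v, tox in ((percent_low, cytotoxic_low), (percent_high, cytotoxic_high))
            if v is not None and not tox]
    if not vals:
        return ActivityCall(compound_id, "not_evaluable_cytotoxic")
    peak = max(vals)
    if peak >= ACTIVE_THRESHOLD:
        return ActivityCall(compound_id, "active")
    if peak >= WEAK_THRESHOLD:
        return ActivityCall(compound_id, "weak")
    return ActivityCall(compound_id, "inactive")


# --------------------------------------------------------------------------
# four-parameter logistic fitting
# --------------------------------------------------------------------------

def fourpl(conc: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float) -> np.ndarray:
    """Variable-slope sigmoid in log10-concentration space."""
    logc = np.log10(conc)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logc) * hill))


@dataclass(eq=False)
class DoseResponseResults:
    """Estimates, uncertainties and diagnostics of a 4PL fit."""

    model: "FourParamLogistic"
    ec50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    degenerate: bool = False
    bse: dict | None = None
    n_iterations: int = 0

    @property
    def params(self) -> dict[str, float]:
        return {"bottom": self.bottom, "top": self.top, "ec50": self.ec50, "hill": self.hill}

    @property
    def extrapolated(self) -> bool:
        """EC50 outside the tested concentration range (estimate reported but
        flagged, since potency beyond the tested range is uncertain)."""
        c = self.model.concentrations
        return not (c.min() <= self.ec50 <= c.max())

    @property
    def nobs(self) -> int:
        return len(self.model.responses)

    def predict(self, conc) -> np.ndarray:
        return fourpl(np.asarray(conc, float), self.bottom, self.top,
                      np.log10(self.ec50), self.hill)

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic dose-response fit",
            "=" * 45,
            f"{'n observations':<22}{self.nobs:>12}",
            f"{'converged':<22}{str(self.converged):>12}",
            f"{'degenerate':<22}{str(self.degenerate):>12}",
            f"{'RSS':<22}{self.rss:>12.5g}",
            "-" * 45,
        ]
        for name in ("bottom", "top", "ec50", "hill"):
            se = (self.bse or {}).get(name)
            se_s = f"{se:>12.4g}" if se is not None and np.isfinite(se) else f"{'--':>12}"
            lines.append(f"{name:<10}{getattr(self, name):>12.4g}  (se {se_s.strip()})")
        if self.extrapolated:
            lines.append("note: EC50 lies outside the tested concentration range")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Concentration–response curve over the data (log-x)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.concentrations
        grid = np.geomspace(c.min() / 3, c.max() * 3, 200)
        ax.semilogx(c, self.model.responses, "o", alpha=0.6, label="data")
        ax.semilogx(grid, self.predict(grid), "-", label="4PL fit")
        ax.axvline(self.ec50, ls="--", color="gray", lw=0.8)
        ax.set_xlabel("concentration (µM)")
        ax.set_ylabel("response")
        ax.legend()
        return ax


class FourParamLogistic:
    """Four-parameter logistic (variable slope) dose–response model.

    Parameters are (bottom, top, EC50, Hill slope); fitting is nonlinear least
    squares on the observed responses at the given concentrations (µM, > 0).
    Requires >= 5 distinct concentrations.
    """

    def __init__(self, concentrations, responses):
        self.concentrations = np.asarray(concentrations, float).ravel()
        self.responses = np.asarray(responses, float).ravel()
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be > 0 (µM)")
        if len(np.unique(self.concentrations)) < 5:
            raise ValueError("need >= 5 distinct concentrations for a 4PL fit")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, conc_col: str = "conc_uM",
                       response_col: str = "fold") -> "FourParamLogistic":
        return cls(df[conc_col].to_numpy(), df[response_col].to_numpy())

    def _initial_guess(self) -> np.ndarray:
        c, y = self.concentrations, self.responses
        bottom, top = float(y.min()), float(y.max())
        half = 0.5 * (bottom + top)
        # EC50 init: linear interpolation of the mean response profile at half-span
        order = np.argsort(c)
        cs, ys = c[order], y[order]
        uc = np.unique(cs)
        my = np.array([ys[cs == u].mean() for u in uc])
        log_ec50 = np.log10(np.median(uc))
        for i in range(len(uc) - 1):
            y0, y1 = my[i], my[i + 1]
            if (y0 - half) * (y1 - half) <= 0 and y0 != y1:
                f = (half - y0) / (y1 - y0)
                log_ec50 = np.log10(uc[i]) + f * (np.log10(uc[i + 1]) - np.log10(uc[i]))
                break
        return np.array([bottom, top, log_ec50, 1.0])

    def fit(self, maxiter: int = 500, tol: float = 1e-8) -> DoseResponseResults:
        """Least-squares fit; on non-convergence the parameters are still
        reported with ``converged=False`` and a warning."""
        y = self.responses
        if np.ptp(y) == 0:
            warnings.warn("constant responses: degenerate dose-response fit", stacklevel=2)
            return DoseResponseResults(self, ec50=float(np.median(self.concentrations)),
                                       hill=0.0, top=float(y[0]), bottom=float(y[0]),
                                       rss=0.0, converged=False, degenerate=True)

        def residuals(theta):
            return fourpl(self.concentrations, *theta) - y

        x0 = self._initial_guess()
        sol = optimize.least_squares(residuals, x0, method="lm", xtol=tol, ftol=tol,
                                     gtol=tol, max_nfev=maxiter * 4)
        bottom, top, log_ec50, hill = sol.x
        if top < bottom:  # canonical orientation: top >= bottom, slope sign flips
            bottom, top, hill = top, bottom, -hill
        converged = bool(sol.success)
        if not converged:
            warnings.warn("4PL fit did not converge; parameters reported anyway", stacklevel=2)
        rss = float(np.sum(sol.fun ** 2))
        bse = None
        try:
            J = sol.jac
            dof = max(len(y) - 4, 1)
            cov = np.linalg.inv(J.T @ J) * rss / dof
            se = np.sqrt(np.diag(cov))
            bse = {"bottom": se[0], "top": se[1],
                   "ec50": se[2] * np.log(10) * 10 ** sol.x[2], "hill": se[3]}
        except np.linalg.LinAlgError:
            pass
        return DoseResponseResults(self, ec50=float(10 ** log_ec50), hill=float(hill),
                                   top=float(top), bottom=float(bottom), rss=rss,
                                   converged=converged, bse=bse, n_iterations=int(sol.nfev))


def fit_4pl(concentrations, responses, **kwargs) -> DoseResponseResults:
    """Convenience wrapper: build a :class:`FourParamLogistic` and fit it."""
    return FourParamLogistic(concentrations, responses).fit(**kwargs)
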