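"""Equilibrium binding fits for fluorescence-anisotropy titrations.

Model: a single binding site at equilibrium, with the labelled peptide at
trace concentration so free protein ~ total protein,

    signal(c) = BL + F * c / (c + K_D)

where ``BL`` is the baseline anisotropy, ``F`` the signal factor (the
anisotropy change at saturation; may be negative) and ``K_D`` the
equilibrium dissociation constant in the concentration units of the
titration (nM throughout).  Buffer-only control titrations can be
subtracted pointwise (with linear interpolation between control
concentrations) before fitting.

When the fitted K_D exceeds the titrated concentration range several-fold
the point estimate is not identified; the result is then flagged and should
be reported as a lower bound ("K_D > max tested concentration"), the usual
convention for weak binders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DataError, FormatError, ParameterError
from .simulate import binding_signal

#: K_D beyond this multiple of the highest tested concentration is reported
#: as a lower bound rather than a point estimate
RANGE_FACTOR = 5.0


@dataclass(frozen=True)
class TitrationSeries:
    """A titration: (concentration, signal, replicate) measurement points
    plus an optional buffer-only control series on the same axis."""

    points: pd.DataFrame = field(repr=False)          # concentration_nM, signal, replicate
    control_points: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for col in ("concentration_nM", "signal", "replicate"):
            if col not in self.points.columns:
                raise FormatError(f"titration points missing column {col!r}")
        if (self.points["concentration_nM"] < 0).any():
            raise DataError("negative concentration")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TitrationSeries":
        """Build from the on-disk layout with a ``series`` column
        (measurement / control)."""
        if "series" not in frame.columns:
            return cls(points=frame.reset_index(drop=True))
        meas = frame[frame["series"] == "measurement"].drop(columns="series")
        ctrl = frame[frame["series"] == "control"].drop(columns="series")
        return cls(
            points=meas.reset_index(drop=True),
            control_points=ctrl.reset_index(drop=True) if len(ctrl) else None,
        )

    def to_frame(self) -> pd.DataFrame:
        meas = self.points.copy()
        meas["series"] = "measurement"
        if self.control_points is None:
            return meas
        ctrl = self.control_points.copy()
        ctrl["series"] = "control"
        return pd.concat([meas, ctrl], ignore_index=True)

    @property
    def n_concentrations(self) -> int:
        return self.points["concentration_nM"].nunique()


def read_titration(path) -> TitrationSeries:
    df = pd.read_csv(path, sep="\t")
    return TitrationSeries.from_frame(df)


def write_titration(series: TitrationSeries, path) -> None:
    series.to_frame().to_csv(path, sep="\t", index=False)


def correct_baseline(series: TitrationSeries) -> TitrationSeries:
    """Subtract the buffer-only control signal, interpolated onto the
    measurement concentrations; clears ``control_points``."""
    if series.control_points is None or len(series.control_points) == 0:
        raise DataError("no control series to subtract")
    ctrl = (
        series.control_points.groupby("concentration_nM")["signal"]
        .mean()
        .sort_index()
    )
    conc = series.points["concentration_nM"].to_numpy(float)
    lo, hi = ctrl.index.min(), ctrl.index.max()
    if conc.min() < lo or conc.max() > hi:
        raise DataError(
            f"control grid [{lo}, {hi}] does not cover measurement range "
            f"[{conc.min()}, {conc.max()}]"
        )
    corr = np.interp(conc, ctrl.index.to_numpy(float), ctrl.to_numpy(float))
    pts = series.points.copy()
    pts["signal"] = pts["signal"].to_numpy(float) - corr
    return TitrationSeries(points=pts, control_points=None)


@dataclass
class BindingResults:
    """Fitted single-site binding parameters with uncertainties."""

    kd: float
    f: float
    bl: float
    kd_se: float
    f_se: float
    bl_se: float
    converged: bool
    kd_exceeds_range: bool
    max_concentration: float
    residual_sd: float
    n_points: int
    se_method: str
    message: str = ""

    @property
    def params(self) -> dict[str, float]:
        return {"bl": self.bl, "f": self.f, "kd": self.kd}

    def predict(self, conc) -> np.ndarray:
        return binding_signal(conc, self.kd, self.f, self.bl)

    def summary(self) -> str:
        lines = ["Single-site equilibrium binding fit",
                 f"  n points: {self.n_points}, converged: {self.converged}"]
        if self.kd_exceeds_range:
            lines.append(
                f"  K_D > {self.max_concentration:g} nM (estimate "
                f"{self.kd:.3g} nM exceeds titrated range; lower bound only)"
            )
        else:
            lines.append(f"  K_D = {self.kd:.4g} +/- {self.kd_se:.2g} nM")
        lines += [
            f"  F   = {self.f:.4g} +/- {self.f_se:.2g}",
            f"  BL  = {self.bl:.4g} +/- {self.bl_se:.2g}",
            f"  residual sd = {self.residual_sd:.3g}  (SEs: {self.se_method})",
        ]
        if self.message:
            lines.append(f"  note: {self.message}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.geomspace(
            max(self.max_concentration * 1e-3, 1e-3), self.max_concentration, 200
        )
        ax.plot(grid, self.predict(grid), "-", color="tab:blue")
        ax.set_xscale("log")
        ax.set_xlabel("concentration (nM)")
        ax.set_ylabel("signal")
        return ax


@dataclass
class BindingModel:
    """Least-squares fit of the single-site binding curve.

    Initialisation: BL0 = minimum signal, F0 = signal span, K_D0 = the
    concentration at half-rise found by interpolation — robust for monotone
    saturation curves.  K_D is box-constrained positive; F and BL are free
    in sign.  Standard errors come from the Jacobian-based covariance
    ("curvature") or from a bootstrap over replicates.
    """

    series: TitrationSeries

    def __post_init__(self) -> None:
        if self.series.n_concentrations < 4:
            raise DataError("need >= 4 distinct concentrations to fit")
        sig = self.series.points["signal"].to_numpy(float)
        if not np.isfinite(sig).all():
            raise DataError("non-finite signal values")
        if np.ptp(sig) == 0:
            raise DataError("constant signal: binding curve is degenerate")

    def initial_values(self) -> tuple[float, float, float]:
        pts = self.series.points.groupby("concentration_nM")["signal"].mean()
        conc = pts.index.to_numpy(float)
        sig = pts.to_numpy(float)
        bl0 = float(sig.min())
        f0 = float(sig[np.argmax(conc)] - sig[np.argmin(conc)])
        if f0 == 0:
            f0 = float(np.ptp(sig))
        half = bl0 + f0 / 2.0 if f0 > 0 else sig.max() + f0 / 2.0
        # concentration at half-rise by interpolation along the curve
        order = np.argsort(conc)
        kd0 = float(np.interp(half, sig[order] if f0 > 0 else sig[order][::-1],
                              conc[order] if f0 > 0 else conc[order][::-1]))
        if kd0 <= 0:
            kd0 = float(np.median(conc[conc > 0])) if (conc > 0).any() else 1.0
        return bl0, f0, kd0

    def fit(
        self,
        se_method: str = "curvature",
        n_boot: int = 500,
        seed: int = 0,
    ) -> BindingResults:
        if se_method not in ("curvature", "bootstrap"):
            raise ParameterError(f"se_method {se_method!r} not 'curvature'/'bootstrap'")
        pts = self.series.points
        conc = pts["concentration_nM"].to_numpy(float)
        sig = pts["signal"].to_numpy(float)
        popt, pcov, ok, msg = _curve_fit(conc, sig, self.initial_values())
        bl, f, kd = popt
        resid = sig - binding_signal(conc, kd, f, bl)
        dof = max(len(sig) - 3, 1)
        residual_sd = float(np.sqrt((resid ** 2).sum() / dof))
        ses = np.sqrt(np.diag(pcov)) if np.isfinite(pcov).all() else np.full(3, np.nan)
        if se_method == "bootstrap" and ok:
            ses = self._bootstrap_ses(n_boot, seed)
        cmax = float(conc.max())
        return BindingResults(
            kd=float(kd), f=float(f), bl=float(bl),
            bl_se=float(ses[0]), f_se=float(ses[1]), kd_se=float(ses[2]),
            converged=ok, kd_exceeds_range=bool(kd > RANGE_FACTOR * cmax),
            max_concentration=cmax, residual_sd=residual_sd,
            n_points=len(sig), se_method=se_method, message=msg,
        )

    def _bootstrap_ses(self, n_boot: int, seed: int) -> np.ndarray:
        """Resample replicates (or points, if a single replicate) and refit."""
        rng = np.random.default_rng(seed)
        pts = self.series.points
        reps = pts["replicate"].unique()
        draws = []
        for _ in range(n_boot):
            if len(reps) > 1:
                take = rng.choice(reps, size=len(reps), replace=True)
                sample = pd.concat([pts[pts["replicate"] == r] for r in take])
            else:
                sample = pts.sample(n=len(pts), replace=True, random_state=rng)
            if sample["concentration_nM"].nunique() < 4:
                continue
            conc = sample["concentration_nM"].to_numpy(float)
            sig = sample["signal"].to_numpy(float)
            popt, _, ok, _ = _curve_fit(conc, sig, self.initial_values())
            if ok:
                draws.append(popt)
        if len(draws) < 2:
            return np.full(3, np.nan)
        return np.std(np.asarray(draws), axis=0, ddof=1)


def _curve_fit(conc, sig, p0):
    def model(c, bl, f, kd):
        return binding_signal(c, kd, f, bl)

    bounds = ([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf])
    p0 = (p0[0], p0[1], max(p0[2], 1e-9))
    try:
        popt, pcov = optimize.curve_fit(
            model, conc, sig, p0=p0, bounds=bounds, maxfev=20000
        )
        return popt, pcov, True, ""
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # non-convergence
        return (np.array(p0), np.full((3, 3), np.nan), False,
                f"fit did not converge: {exc}")


def fit_binding(
    series: TitrationSeries,
    se_method: str = "curvature",
    n_boot: int = 500,
    seed: int = 0,
) -> BindingResults:
    """Functional wrapper: fit the single-site model to a titration."""
    return BindingModel(series).fit(se_method=se_method, n_boot=n_boot, seed=seed)
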