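"""One-site saturation binding with a nonspecific component.

Model (total binding):

    Y(X) = Bmax * X / (Kd + X) + NS * X + B0

with X the free ligand concentration (nM), Kd the dissociation constant,
Bmax the maximal specific signal, NS the linear nonspecific slope, and B0 a
constant background.  B0 is included because plate blanks are subtracted
imperfectly; it can be disabled.

Fitting is unweighted nonlinear least squares (lmfit/Levenberg-Marquardt)
with Kd log-parameterized to enforce positivity; standard errors come from
the Jacobian at the optimum (the Kd error is transformed from the log
scale).  An optional 1/Y^2 weighting is available.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "BindingCurve",
    "BindingFit",
    "total_binding",
    "subtract_background",
    "fit_total_binding",
    "cheng_prusoff_ki",
    "read_curve_csv",
    "write_curve_csv",
]


@dataclasses.dataclass(frozen=True)
class BindingCurve:
    """Concentration/signal pairs; duplicates in X are replicates."""

    X: np.ndarray   # nM, >= 0
    Y: np.ndarray   # signal (absorbance units)
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        object.__setattr__(self, "Y", np.asarray(self.Y, dtype=float))
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must have equal lengths")
        if (self.X < 0).any():
            raise ValueError("concentrations must be non-negative")

    @property
    def n_distinct(self) -> int:
        return np.unique(self.X).size


@dataclasses.dataclass(frozen=True)
class BindingFit:
    Kd: float           # nM
    Bmax: float
    NS: float           # signal per nM
    B0: float
    se_Kd: float
    se_Bmax: float
    se_NS: float
    se_B0: float
    rss: float
    converged: bool
    kd_unidentifiable: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        return total_binding(X, self.Kd, self.Bmax, self.NS, self.B0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def total_binding(X, Kd: float, Bmax: float, NS: float = 0.0, B0: float = 0.0):
    """Pointwise one-site total+nonspecific model evaluation."""
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    X = np.asarray(X, dtype=float)
    return Bmax * X / (Kd + X) + NS * X + B0


def subtract_background(curve: BindingCurve, blank_signals: Sequence[float]) -> BindingCurve:
    """Subtract the mean of no-coat blank wells from every signal."""
    blanks = np.asarray(blank_signals, dtype=float)
    if blanks.size == 0:
        raise ValueError("blank signal list is empty")
    return BindingCurve(X=curve.X, Y=curve.Y - blanks.mean(), replicate=curve.replicate)


def _initial_guess(X: np.ndarray, Y: np.ndarray) -> dict[str, float]:
    order = np.argsort(X)
    Xs, Ys = X[order], Y[order]
    b0 = float(Ys[Xs == Xs.min()].mean())
    top = float(Ys[Xs == Xs.max()].mean())
    # nonspecific slope from the top two distinct concentrations
    distinct = np.unique(Xs)
    ns = 0.0
    if distinct.size >= 2:
        x1, x2 = distinct[-2], distinct[-1]
        y1 = float(Ys[Xs == x1].mean())
        y2 = float(Ys[Xs == x2].mean())
        ns = max(0.0, (y2 - y1) / (x2 - x1))
    bmax = max(top - b0 - ns * distinct[-1], 1e-6)
    half = b0 + 0.5 * bmax
    above = distinct[
        [float(Ys[Xs == x].mean()) >= half for x in distinct]
    ]
    kd0 = float(above[0]) if above.size else float(np.median(distinct))
    kd0 = max(kd0, 1e-9)
    return {"Kd": kd0, "Bmax": bmax, "NS": ns, "B0": b0}


def fit_total_binding(
    curve: BindingCurve,
    init: dict[str, float] | None = None,
    include_background: bool = True,
    weight_inverse_y2: bool = False,
) -> BindingFit:
    """Least-squares fit of the one-site total+nonspecific model.

    Requires at least 4 distinct concentrations.  Kd is fitted on a log10
    scale (positivity by construction); Bmax and NS are bounded below by 0.
    Non-convergence is flagged rather than raised; a flat curve (fitted
    Bmax indistinguishable from 0) sets ``kd_unidentifiable``.
    """
    X, Y = curve.X, curve.Y
    if curve.n_distinct < 4:
        raise ValueError("need at least 4 distinct concentrations")
    guess = _initial_guess(X, Y)
    if init:
        guess.update(init)

    params = lmfit.Parameters()
    params.add("logKd", value=np.log10(guess["Kd"]), min=-12.0, max=9.0)
    params.add("Bmax", value=guess["Bmax"], min=0.0)
    params.add("NS", value=guess["NS"], min=0.0)
    params.add("B0", value=guess["B0"], vary=include_background)
    if not include_background:
        params["B0"].value = 0.0

    weights = 1.0 / np.maximum(np.abs(Y), 1e-6) if weight_inverse_y2 else None

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = total_binding(X, 10.0 ** p["logKd"].value, p["Bmax"].value,
                              p["NS"].value, p["B0"].value)
        r = model - Y
        return r * weights if weights is not None else r

    result = lmfit.minimize(residual, params, method="leastsq")
    p = result.params
    kd = 10.0 ** p["logKd"].value

    def se(name: str) -> float:
        err = p[name].stderr
        return float(err) if err is not None and np.isfinite(err) else np.nan

    se_kd = np.log(10.0) * kd * se("logKd")
    rss = float(np.sum(np.asarray(result.residual) ** 2))
    bmax = float(p["Bmax"].value)
    noise_scale = np.sqrt(rss / max(1, result.nfree)) if result.nfree else 0.0
    signal_scale = max(float(np.ptp(Y)), abs(float(p["B0"].value)), 1e-12)
    unidentifiable = bool(bmax <= max(3.0 * noise_scale, 1e-6 * signal_scale))
    return BindingFit(
        Kd=float(kd),
        Bmax=bmax,
        NS=float(p["NS"].value),
        B0=float(p["B0"].value),
        se_Kd=float(se_kd),
        se_Bmax=se("Bmax"),
        se_NS=se("NS"),
        se_B0=se("B0") if include_background else 0.0,
        rss=rss,
        converged=bool(result.success),
        kd_unidentifiable=unidentifiable,
    )


def cheng_prusoff_ki(apparent_kd: float, competitor_conc: float, competitor_kd: float) -> float:
    """Ki of a competitor from the apparent Kd shift (Cheng-Prusoff)."""
    return apparent_kd / (1.0 + competitor_conc / competitor_kd)


def read_curve_csv(path: str | Path) -> BindingCurve:
    df = pd.read_csv(path)
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return BindingCurve(
        X=df["concentration_nM"].to_numpy(dtype=float),
        Y=df["signal"].to_numpy(dtype=float),
        replicate=rep,
    )


def write_curve_csv(curve: BindingCurve, path: str | Path) -> None:
    data = {"concentration_nM": curve.X, "signal": curve.Y}
    if curve.replicate is not None:
        data["replicate"] = curve.replicate
    pd.DataFrame(data).to_csv(path, index=False)
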