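"""1:1 Langmuir SPR kinetics: sensorgram simulation and fitting.

The model is the simple bimolecular surface interaction A + B ⇌ AB with no
mass-transport limitation or drift:

    association   R(t) = Req · (1 − exp(−(kon·C + koff)·t)),
                  Req  = Rmax · C / (C + Kd),      Kd = koff / kon
    dissociation  R(t) = R_end · exp(−koff · (t − t_off))

Fitting follows statsmodels conventions: :class:`LangmuirModel` is built
from a list of sensorgrams and its :meth:`~LangmuirModel.fit` returns a
:class:`KineticResults` carrying the estimates, per-curve residuals and a
``summary()`` table.  A fixed multistart grid over (kon, koff) decades
guards against local minima; steady-state (hyperbola) fitting and the
Scatchard linearization are provided for cross-checking Kd.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "Sensorgram",
    "KineticResults",
    "SteadyStateResults",
    "LangmuirModel",
    "simulate_sensorgram",
    "fit_kinetic",
    "fit_steady_state",
    "read_sensorgram_csv",
    "write_sensorgram_csv",
]

# fixed multistart grid (documented, reproducible)
KON_GRID = 10.0 ** np.arange(3, 8)    # 1e3 .. 1e7 M^-1 s^-1
KOFF_GRID = 10.0 ** np.arange(-4, 0)  # 1e-4 .. 1e-1 s^-1


@dataclass
class Sensorgram:
    """One SPR time course at a single analyte concentration.

    ``t_assoc_end`` marks the end of the association phase (injection stop);
    times beyond it are dissociation.  Times before zero, when present, are
    pre-injection baseline.
    """

    time: np.ndarray          # s
    response: np.ndarray      # RU
    analyte_concentration: float  # M
    t_assoc_end: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.response = np.asarray(self.response, float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.analyte_concentration <= 0:
            raise ValueError("analyte concentration must be positive")
        if self.t_assoc_end <= self.time[0]:
            raise ValueError("association must precede dissociation")

    def baseline_subtracted(self) -> "Sensorgram":
        """Subtract the pre-injection (t < 0) mean, when such points exist."""
        pre = self.response[self.time < 0]
        if pre.size == 0:
            return self
        return Sensorgram(self.time, self.response - pre.mean(),
                          self.analyte_concentration, self.t_assoc_end)

    def plateau(self) -> float:
        """Mean response over the last 10% of the association phase."""
        assoc = (self.time >= 0) & (self.time <= self.t_assoc_end)
        t = self.time[assoc]
        keep = t >= self.t_assoc_end - 0.1 * (self.t_assoc_end - max(0.0, t[0]))
        return float(self.response[assoc][keep].mean())


def langmuir_curve(t: np.ndarray, conc: float, kon: float, koff: float,
                   rmax: float, t_assoc_end: float) -> np.ndarray:
    """Noise-free 1:1 model response over association + dissociation."""
    t = np.asarray(t, float)
    kon = max(kon, 1e-300)  # guard against underflow during log-space optimisation
    kd = koff / kon
    req = rmax * conc / (conc + kd)
    kobs = kon * conc + koff
    r = np.zeros_like(t)
    assoc = (t >= 0) & (t <= t_assoc_end)
    dissoc = t > t_assoc_end
    with np.errstate(over="ignore", invalid="ignore"):
        r[assoc] = req * (1.0 - np.exp(-kobs * t[assoc]))
        r_end = req * (1.0 - np.exp(-kobs * t_assoc_end))
        r[dissoc] = r_end * np.exp(-koff * (t[dissoc] - t_assoc_end))
    return np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)


def simulate_sensorgram(
    kon: float,
    koff: float,
    rmax: float,
    conc: float,
    t_assoc: float = 300.0,
    t_dissoc: float = 300.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 1.0,
) -> Sensorgram:
    """Simulate one 1:1 sensorgram with Gaussian noise of sd ``noise_sd`` RU."""
    if min(kon, koff, rmax, conc, t_assoc, t_dissoc) <= 0:
        raise ValueError("rates, Rmax, concentration and phase lengths must be positive")
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    r = langmuir_curve(t, conc, kon, koff, rmax, t_assoc)
    if noise_sd > 0:
        r = r + np.random.default_rng(seed).normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(time=t, response=r, analyte_concentration=conc, t_assoc_end=t_assoc)


@dataclass
class KineticResults:
    """Global 1:1 fit results across all curves."""

    kon: float               # 1/(M s)
    koff: float              # 1/s
    rmax: float              # RU
    per_curve_rms: list[float]
    n_curves: int
    n_points: int
    converged: bool
    cost: float

    @property
    def kd(self) -> float:
        return self.koff / self.kon

    def summary(self) -> str:
        lines = [
            "1:1 Langmuir kinetic fit",
            "=" * 40,
            f"curves:         {self.n_curves}  ({self.n_points} points)",
            f"kon  [1/(M s)]: {self.kon:.4g}",
            f"koff [1/s]:     {self.koff:.4g}",
            f"Kd   [M]:       {self.kd:.4g}  ({self.kd * 1e6:.3g} uM)",
            f"Rmax [RU]:      {self.rmax:.4g}",
            f"residual RMS per curve [RU]: "
            + ", ".join(f"{r:.3g}" for r in self.per_curve_rms),
            f"converged:      {self.converged}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kon": self.kon, "koff": self.koff, "Kd": self.kd, "Rmax": self.rmax,
            "per_curve_rms": self.per_curve_rms, "n_curves": self.n_curves,
        }


class LangmuirModel:
    """statsmodels-style model object: build from sensorgrams, then ``fit()``."""

    def __init__(self, curves: Sequence[Sensorgram]):
        if not curves:
            raise ValueError("need at least one sensorgram")
        self.curves = [c.baseline_subtracted() for c in curves]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LangmuirModel":
        """Build from a tidy table with columns time_s, response_RU, conc_M, phase."""
        curves = []
        for conc, grp in df.groupby("conc_M"):
            grp = grp.sort_values("time_s")
            assoc = grp[grp["phase"] == "association"]
            if assoc.empty:
                raise ValueError(f"concentration {conc}: no association phase")
            curves.append(
                Sensorgram(
                    time=grp["time_s"].to_numpy(),
                    response=grp["response_RU"].to_numpy(),
                    analyte_concentration=float(conc),
                    t_assoc_end=float(assoc["time_s"].max()),
                )
            )
        return cls(curves)

    def _residuals(self, log_params: np.ndarray) -> np.ndarray:
        kon, koff, rmax = np.exp(np.clip(log_params, -300.0, 300.0))
        res = []
        for c in self.curves:
            pred = langmuir_curve(c.time, c.analyte_concentration, kon, koff,
                                  rmax, c.t_assoc_end)
            mask = c.time >= 0
            res.append(c.response[mask] - pred[mask])
        return np.concatenate(res)

    def fit(self, multistart: bool = True) -> KineticResults:
        """Global nonlinear least squares of (kon, koff, Rmax) over all curves.

        Parameters are fitted in log space (positivity by construction); a
        fixed grid of (kon, koff) decades seeds the optimizer and the best
        converged solution wins.
        """
        rmax0 = max(float(c.response.max()) for c in self.curves) * 1.2
        starts = (
            [(kon, koff) for kon in KON_GRID for koff in KOFF_GRID]
            if multistart else [(1e5, 1e-2)]
        )
        best = None
        for kon0, koff0 in starts:
            x0 = np.log([kon0, koff0, rmax0])
            try:
                sol = optimize.least_squares(self._residuals, x0, method="lm",
                                             max_nfev=4000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("kinetic fit failed from every start point")
        kon, koff, rmax = np.exp(best.x)
        per_curve = []
        for c in self.curves:
            pred = langmuir_curve(c.time, c.analyte_concentration, kon, koff,
                                  rmax, c.t_assoc_end)
            mask = c.time >= 0
            per_curve.append(float(np.sqrt(np.mean((c.response[mask] - pred[mask]) ** 2))))
        n_points = int(sum((c.time >= 0).sum() for c in self.curves))
        return KineticResults(
            kon=float(kon), koff=float(koff), rmax=float(rmax),
            per_curve_rms=per_curve, n_curves=len(self.curves),
            n_points=n_points, converged=bool(best.success), cost=float(best.cost),
        )


def fit_kinetic(curves: Sequence[Sensorgram]) -> KineticResults:
    """Convenience wrapper: ``LangmuirModel(curves).fit()``."""
    return LangmuirModel(curves).fit()


@dataclass
class SteadyStateResults:
    """Hyperbola fit of plateau responses plus the Scatchard linearization."""

    kd: float
    rmax: float
    scatchard_slope: float
    scatchard_intercept: float
    n_points: int

    @property
    def scatchard_kd(self) -> float:
        return -1.0 / self.scatchard_slope

    def summary(self) -> str:
        return "\n".join([
            "Steady-state (Req vs C) fit",
            "=" * 40,
            f"points:            {self.n_points}",
            f"Kd   [M]:          {self.kd:.4g}  ({self.kd * 1e6:.3g} uM)",
            f"Rmax [RU]:         {self.rmax:.4g}",
            f"Scatchard slope:   {self.scatchard_slope:.4g}  (Kd = {self.scatchard_kd * 1e6:.3g} uM)",
        ])


def fit_steady_state(plateaus: Sequence[tuple[float, float]]) -> SteadyStateResults:
    """Fit Req = Rmax·C/(C + Kd) to (concentration, plateau) points.

    Also returns the Scatchard linearization (Req/C vs Req; slope = −1/Kd),
    which equals the nonlinear Kd exactly on noise-free data and serves as a
    classical cross-check under noise.
    """
    if len(plateaus) < 3:
        raise ValueError("need at least 3 concentration points")
    conc = np.array([p[0] for p in plateaus], float)
    req = np.array([p[1] for p in plateaus], float)
    if np.allclose(req, req[0]):
        raise ValueError("plateau responses are all equal: no curvature to fit")
    kd0 = float(np.median(conc))
    rmax0 = float(req.max() * 1.5)
    popt, _ = optimize.curve_fit(
        lambda c, rmax, kd: rmax * c / (c + kd), conc, req,
        p0=[rmax0, kd0], maxfev=10000,
    )
    rmax, kd = float(popt[0]), float(popt[1])
    slope, intercept = np.polyfit(req, req / conc, 1)
    return SteadyStateResults(kd=kd, rmax=rmax, scatchard_slope=float(slope),
                              scatchard_intercept=float(intercept), n_points=len(conc))


# ---------------------------------------------------------------------------
# CSV I/O  (columns: time_s, response_RU, conc_M, phase)


def write_sensorgram_csv(curves: Sequence[Sensorgram], path: str) -> None:
    frames = []
    for c in curves:
        phase = np.where(c.time < 0, "baseline",
                         np.where(c.time <= c.t_assoc_end, "association", "dissociation"))
        frames.append(pd.DataFrame({
            "time_s": c.time, "response_RU": c.response,
            "conc_M": c.analyte_concentration, "phase": phase,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensorgram_csv(path: str) -> list[Sensorgram]:
    df = pd.read_csv(path)
    required = {"time_s", "response_RU", "conc_M", "phase"}
    if not required <= set(df.columns):
        raise ValueError(f"sensorgram CSV must have columns {sorted(required)}")
    return LangmuirModel.from_dataframe(df).curves
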