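"""Assay math and Michaelis-Menten kinetics for chromogenic lipase assays.

Esterolytic activity is followed as p-nitrophenol release (A410) in
microtiter plates; absorbance slopes convert to specific rates via the
Lambert-Beer law using the assay's effective path length (0.58 cm for
165 µL in a 96-well plate) and the p-nitrophenol extinction coefficient
at the assay pH (7194 M⁻¹cm⁻¹).  Initial rates over a substrate series
are fitted to v = Vmax·S/(Km + S) by nonlinear least squares.

Fitted parameters are reported as *observed* Vmax/Km: no correction is
attempted for limited substrate solubility or interfacial effects at
high nominal concentrations of long-chain esters, so the values compare
variants under one protocol rather than estimate true kinetic constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "AssayConstants",
    "SaturationDataset",
    "MMFit",
    "MMFitError",
    "ResidualActivitySeries",
    "absorbance_slope_to_rate",
    "fit_michaelis_menten",
    "residual_activity",
    "rfu_slope_summary",
    "generate_saturation_data",
    "load_reference_mm_params",
    "DEFAULT_CONCENTRATIONS_MM",
    "PNPO_CONCENTRATIONS_MM",
]

# substrate series used for saturation assays (mM); pNPO extends to 2.5 mM
DEFAULT_CONCENTRATIONS_MM: tuple[float, ...] = (0.06, 0.125, 0.25, 0.5, 0.75, 1.0, 1.25, 1.875)
PNPO_CONCENTRATIONS_MM: tuple[float, ...] = DEFAULT_CONCENTRATIONS_MM + (2.5,)


@dataclass(frozen=True)
class AssayConstants:
    """Microtiter-plate assay constants.

    path_length: effective optical path, cm (0.58 cm at 165 µL/well).
    extinction_coefficient: p-nitrophenol, M⁻¹cm⁻¹ at the assay pH.
    reaction_volume_uL: total reaction volume.
    enzyme_mass_ng: enzyme loaded per reaction (120 ng is the standardized
    wildtype loading; always override for other preparations).
    """

    path_length: float = 0.58
    extinction_coefficient: float = 7194.0
    reaction_volume_uL: float = 165.0
    enzyme_mass_ng: float = 120.0

    def __post_init__(self) -> None:
        for name in ("path_length", "extinction_coefficient", "reaction_volume_uL", "enzyme_mass_ng"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def absorbance_slope_to_rate(slope: float, constants: AssayConstants = AssayConstants()) -> float:
    """Convert an absorbance slope (A/min) to µmol product · mg⁻¹ · min⁻¹.

    Lambert-Beer gives the product formation rate in M/min; multiplying by
    the reaction volume in µL yields µmol/min (M·µL = µmol), and dividing
    by the enzyme mass in mg gives the specific rate.
    """
    if slope < 0:
        raise ValueError("absorbance slope must be non-negative")
    molar_per_min = slope / (constants.extinction_coefficient * constants.path_length)
    umol_per_min = molar_per_min * constants.reaction_volume_uL
    mg = constants.enzyme_mass_ng * 1e-6
    return umol_per_min / mg


@dataclass(frozen=True)
class SaturationDataset:
    """Concentration-rate series for one substrate.

    ``points`` columns: concentration_mM, rate (µmol·mg⁻¹·min⁻¹),
    replicate.  Fitting requires at least 4 distinct concentrations.
    """

    substrate: str
    points: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"concentration_mM", "rate", "replicate"}
        if not required <= set(self.points.columns):
            raise ValueError(f"points must have columns {sorted(required)}")
        if (self.points["concentration_mM"] <= 0).any():
            raise ValueError("substrate concentrations must be positive")

    @classmethod
    def from_arrays(
        cls,
        substrate: str,
        concentrations: Sequence[float],
        rates: Sequence[float],
        replicates: Sequence | None = None,
    ) -> "SaturationDataset":
        if replicates is None:
            replicates = [1] * len(concentrations)
        return cls(
            substrate,
            pd.DataFrame(
                {
                    "concentration_mM": list(concentrations),
                    "rate": list(rates),
                    "replicate": list(replicates),
                }
            ),
        )

    @classmethod
    def read_tsv(cls, path, substrate: str | None = None) -> "SaturationDataset":
        df = pd.read_csv(path, sep="\t", comment="#")
        if "replicate" not in df.columns:
            df["replicate"] = 1
        name = substrate or (str(df["substrate"].iloc[0]) if "substrate" in df.columns else "unknown")
        return cls(name, df[["concentration_mM", "rate", "replicate"]])

    def n_distinct_concentrations(self) -> int:
        return self.points["concentration_mM"].nunique()


class MMFitError(RuntimeError):
    """Raised when the Michaelis-Menten fit does not converge."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class MMFit:
    """Observed Michaelis-Menten parameters with standard errors."""

    substrate: str
    vmax: float
    km: float
    vmax_se: float
    km_se: float
    n_points: int
    residual_sum_of_squares: float
    converged: bool
    message: str

    def to_dict(self) -> dict:
        return {
            "substrate": self.substrate,
            "observed_vmax": self.vmax,
            "observed_km_mM": self.km,
            "vmax_se": self.vmax_se,
            "km_se": self.km_se,
            "n_points": self.n_points,
            "rss": self.residual_sum_of_squares,
            "converged": self.converged,
            "message": self.message,
        }


def michaelis_menten(s, vmax: float, km: float):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def fit_michaelis_menten(data: SaturationDataset) -> MMFit:
    """Unweighted nonlinear least squares of v = Vmax·S/(Km + S).

    Initialization: Vmax₀ = max observed rate; Km₀ = the concentration
    whose rate is nearest Vmax₀/2.  Positivity is enforced by fitting
    (log Vmax, log Km); standard errors come from the Jacobian at the
    optimum and transfer to the natural scale by the delta method.
    Replicates are pooled.  Non-convergence raises :class:`MMFitError`
    with diagnostics attached.
    """
    if data.n_distinct_concentrations() < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")
    s = data.points["concentration_mM"].to_numpy(dtype=float)
    v = data.points["rate"].to_numpy(dtype=float)
    if (v < 0).any():
        raise ValueError("rates must be non-negative")
    vmax0 = float(v.max())
    if vmax0 <= 0:
        raise ValueError("all rates are zero; nothing to fit")
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2.0))])

    def resid(theta):
        vmax, km = np.exp(theta)
        return michaelis_menten(s, vmax, km) - v

    sol = least_squares(
        resid,
        x0=np.log([vmax0, km0]),
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=10000,
    )
    diagnostics = {
        "status": sol.status,
        "message": sol.message,
        "cost": float(sol.cost),
        "nfev": sol.nfev,
        "x0": [vmax0, km0],
    }
    if not sol.success:
        raise MMFitError(f"Michaelis-Menten fit failed: {sol.message}", diagnostics)
    vmax, km = np.exp(sol.x)
    n, p = len(v), 2
    rss = float(2 * sol.cost)
    dof = max(n - p, 1)
    jtj = sol.jac.T @ sol.jac
    try:
        cov_log = np.linalg.inv(jtj) * (rss / dof)
        se_log = np.sqrt(np.diag(cov_log))
    except np.linalg.LinAlgError:
        se_log = np.full(2, np.nan)
    # delta method: se(exp(x)) = exp(x) * se(x)
    return MMFit(
        substrate=data.substrate,
        vmax=float(vmax),
        km=float(km),
        vmax_se=float(vmax * se_log[0]),
        km_se=float(km * se_log[1]),
        n_points=n,
        residual_sum_of_squares=rss,
        converged=True,
        message=str(sol.message),
    )


@dataclass(frozen=True)
class ResidualActivitySeries:
    """Residual activity (% of untreated) across condition values."""

    condition: str
    percent: dict[float, float]


def residual_activity(
    treated_rates: Mapping[float, float],
    untreated_rate: float,
    condition: str = "condition",
) -> ResidualActivitySeries:
    """Express treated rates as percent of the untreated sample's rate."""
    if untreated_rate <= 0:
        raise ValueError("untreated rate must be strictly positive")
    return ResidualActivitySeries(
        condition,
        {float(k): 100.0 * v / untreated_rate for k, v in treated_rates.items()},
    )


def rfu_slope_summary(
    times: Sequence[float],
    rfu: Sequence[float],
    r2_threshold: float = 0.99,
    min_points: int = 3,
) -> tuple[float, int]:
    """OLS slope (RFU/min) over the longest linear prefix of a time series.

    Scans prefixes from the full series down to ``min_points`` and returns
    the slope of the longest one whose linear fit has R² >= the threshold,
    together with the number of points used.  An exactly constant prefix
    counts as linear (slope 0).  If no prefix qualifies, the shortest
    window is used.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(rfu, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and rfu must be matching 1-D sequences")
    if len(t) < min_points:
        raise ValueError(f"need at least {min_points} time points")

    def ols(n: int) -> tuple[float, float]:
        tt, yy = t[:n], y[:n]
        slope, intercept = np.polyfit(tt, yy, 1)
        fitted = slope * tt + intercept
        ss_res = float(((yy - fitted) ** 2).sum())
        ss_tot = float(((yy - yy.mean()) ** 2).sum())
        if ss_tot == 0.0:
            r2 = 1.0 if ss_res < 1e-12 else 0.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        return float(slope), r2

    for n in range(len(t), min_points - 1, -1):
        slope, r2 = ols(n)
        if r2 >= r2_threshold:
            return slope, n
    slope, _ = ols(min_points)
    return slope, min_points


def generate_saturation_data(
    vmax: float,
    km: float,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS_MM,
    noise_cv: float = 0.0,
    replicates: int = 1,
    seed: int | None = None,
    substrate: str = "synthetic",
) -> SaturationDataset:
    """Synthetic Michaelis-Menten rate data with multiplicative noise.

    Rates are v(S)·(1 + CV·z) with z ~ N(0, 1), i.i.d. per observation;
    deterministic under a fixed seed.  ``noise_cv=0`` returns the exact
    hyperbola evaluated at the concentration series.
    """
    if vmax <= 0 or km <= 0:
        raise ValueError("vmax and km must be strictly positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    conc, rates, reps = [], [], []
    for rep in range(1, replicates + 1):
        for s in concentrations:
            mean = vmax * s / (km + s)
            noise = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
            conc.append(float(s))
            rates.append(mean * (1.0 + noise))
            reps.append(rep)
    return SaturationDataset.from_arrays(substrate, conc, rates, reps)


def load_reference_mm_params() -> pd.DataFrame:
    """Packaged observed Vmax/Km parameter sets (wildtype and P5F3 BSLA).

    Columns: variant, substrate, vmax, vmax_se, km_mM, km_se.  Vmax in
    µmol p-nitrophenol · mg⁻¹ · min⁻¹; Km in mM.
    """
    import io

    text = (resources.files("delrand") / "data" / "bsla_mm_observed_params.tsv").read_text()
    return pd.read_csv(io.StringIO(text), sep="\t")
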