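"""Vesicle-assay arithmetic: leakage fractions, lipid exchange, partition fit.

Three standard pieces of plate-reader algebra used alongside the simulations:

* fractional leakage from a dye-release assay, normalized between a
  no-peptide negative control and a detergent (100% leakage) positive
  control;
* lipid-exchange (fusion) percentage from an NBD/Rhodamine FRET dilution
  assay, the baseline-subtracted ratio of measured to positive-control NBD
  fluorescence;
* a mole-fraction partition coefficient fitted to tryptophan-fluorescence
  titrations, ``I([L]) = 1 + (Imax − 1)·Kp·[L] / ([W] + Kp·[L])`` with the
  molar concentration of water ``[W] = 55.3 M``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ControlError, FitError, InputError

logger = logging.getLogger(__name__)

WATER_MOLARITY = 55.3  # mol/L, molar concentration of water


@dataclass
class LeakageResult:
    fraction: float
    clipped: bool


def fractional_leakage(f_sample: float, f_negative: float, f_positive: float
                       ) -> LeakageResult:
    """Fractional leakage ``(F − F0) / (F100 − F0)``, clipped to [0, 1].

    ``f_negative`` is the no-peptide reading and ``f_positive`` the
    Triton-lysed 100%-leakage reading; the formula is affine-invariant, so a
    common gain or offset on all three readings cancels.  Works for both
    dequenching readouts (signal rises with leakage) and donor-quenching
    readouts (signal falls), provided the controls are given in the same
    orientation as the samples.
    """
    if f_positive == f_negative:
        raise ControlError("positive and negative controls are identical")
    frac = (f_sample - f_negative) / (f_positive - f_negative)
    clipped = not 0.0 <= frac <= 1.0
    if clipped:
        logger.info("leakage fraction %.4f clipped to [0, 1]", frac)
    return LeakageResult(fraction=float(np.clip(frac, 0.0, 1.0)), clipped=clipped)


def leakage_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`fractional_leakage` to a tidy assay table.

    Expects columns ``peptide_name, P_to_L_ratio, F_sample, F_negative,
    F_positive`` (extra columns such as ``replicate_id`` pass through);
    returns the table with ``fraction`` and ``clipped`` columns added, plus
    per-(peptide, ratio) mean ± standard error when replicates are present.
    """
    required = {"peptide_name", "P_to_L_ratio", "F_sample", "F_negative",
                "F_positive"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"assay table missing column(s): {sorted(missing)}")
    if (table["P_to_L_ratio"] <= 0).any():
        raise InputError("P:L ratios must be positive")
    out = table.copy()
    res = [
        fractional_leakage(r.F_sample, r.F_negative, r.F_positive)
        for r in out.itertuples()
    ]
    out["fraction"] = [r.fraction for r in res]
    out["clipped"] = [r.clipped for r in res]
    return out


def summarize_replicates(table: pd.DataFrame, value: str = "fraction"
                         ) -> pd.DataFrame:
    """Mean ± standard error per (peptide, P:L), with replicate count n."""
    g = table.groupby(["peptide_name", "P_to_L_ratio"])[value]
    out = g.agg(mean="mean", n="count")
    out["sem"] = g.sem(ddof=1).fillna(0.0)
    return out.reset_index()


def lipid_exchange_fraction(nbd_measured: float, nbd_positive: float,
                            nbd_negative: float = 0.0) -> float:
    """Lipid-exchange percentage from NBD fluorescence.

    Baseline-subtracted ratio of the measured NBD fluorescence to the
    positive-control (fully mixed) NBD fluorescence, as a percentage.
    """
    if nbd_positive <= nbd_negative:
        raise ControlError("positive control must exceed negative control")
    return 100.0 * (nbd_measured - nbd_negative) / (nbd_positive - nbd_negative)


# ---------------------------------------------------------------------------
# Mole-fraction partition coefficient
# ---------------------------------------------------------------------------

@dataclass
class BindingSeries:
    """A tryptophan-fluorescence titration.

    ``fold_increase`` is the fluorescence fold increase I relative to the
    no-lipid reading; an optional ``scatter_baseline`` (free-tryptophan
    readings at the same lipid concentrations) is subtracted, as fold-increase
    excess over 1, to correct for lipid scattering.
    """

    lipid_concentrations: np.ndarray  # molar
    fold_increase: np.ndarray
    scatter_baseline: np.ndarray | None = None
    water_molarity: float = WATER_MOLARITY

    def __post_init__(self):
        self.lipid_concentrations = np.asarray(self.lipid_concentrations, float)
        self.fold_increase = np.asarray(self.fold_increase, float)
        if self.lipid_concentrations.shape != self.fold_increase.shape:
            raise InputError("lipid and fluorescence arrays differ in length")
        if np.any(self.lipid_concentrations < 0):
            raise InputError("lipid concentrations must be nonnegative")
        if np.any(self.fold_increase < 0):
            raise InputError("fold increase must be nonnegative")

    def corrected(self) -> np.ndarray:
        if self.scatter_baseline is None:
            return self.fold_increase
        base = np.asarray(self.scatter_baseline, float)
        return self.fold_increase - (base - 1.0)


def partition_model(lipid: np.ndarray, kp: float, imax: float,
                    water_molarity: float = WATER_MOLARITY) -> np.ndarray:
    """Mole-fraction partition binding curve.

    ``I([L]) = 1 + (Imax − 1)·Kp[L]/([W] + Kp[L])``: I → 1 as Kp → 0 and
    I → Imax in the saturating limit Kp[L] ≫ [W].
    """
    lipid = np.asarray(lipid, float)
    return 1.0 + (imax - 1.0) * kp * lipid / (water_molarity + kp * lipid)


@dataclass
class PartitionFit:
    kp: float
    imax: float
    kp_stderr: float
    imax_stderr: float
    residuals: np.ndarray
    rmsd: float


def fit_partition_coefficient(series: BindingSeries,
                              p0: tuple[float, float] | None = None
                              ) -> PartitionFit:
    """Least-squares fit of (Kp, Imax) to a binding series.

    Requires ≥ 4 lipid concentrations spanning at least one order of
    magnitude.  Raises :class:`~porenet.errors.FitError` on non-convergence.
    """
    lipid = series.lipid_concentrations
    y = series.corrected()
    positive = lipid[lipid > 0]
    if len(lipid) < 4:
        raise InputError("need at least 4 lipid concentrations")
    if positive.size == 0 or positive.max() / positive.min() < 10.0:
        raise InputError(
            "lipid concentrations must span at least one order of magnitude"
        )
    if p0 is None:
        imax0 = max(float(y.max()), 1.1)
        # half-saturation guess: Kp·[L_mid] ≈ [W]
        mid = float(np.median(positive))
        p0 = (series.water_molarity / mid, imax0)

    def model(l, kp, imax):
        return partition_model(l, kp, imax, series.water_molarity)

    try:
        popt, pcov = curve_fit(model, lipid, y, p0=p0,
                               bounds=([0.0, 1.0], [np.inf, np.inf]),
                               maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"partition fit failed to converge: {exc}") from exc
    resid = y - model(lipid, *popt)
    err = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan, np.nan)
    return PartitionFit(
        kp=float(popt[0]), imax=float(popt[1]),
        kp_stderr=float(err[0]), imax_stderr=float(err[1]),
        residuals=resid, rmsd=float(np.sqrt(np.mean(resid ** 2))),
    )
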