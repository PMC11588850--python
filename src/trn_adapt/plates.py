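"""Phenotyping-plate kinetics to binary growth calls, comparisons, and PCA.

Multiwell phenotype plates record opacity over ~48 h per well, each well
holding a different substrate (carbon, nitrogen, sulfur or phosphorus
source) plus negative-control wells with no substrate.  The calling
pipeline is:

1. smooth each well's trace with a Savitzky-Golay filter (window 51,
   polynomial degree 3 — classical SG needs an odd window, so an even
   request is rounded up);
2. take the maximum smoothed signal per well;
3. form a control distribution from the negative-control wells' maxima and
   one-sided z-test every substrate well against it (growth = higher
   opacity), Bonferroni-corrected over the plate's tested wells;
4. call growth where the adjusted p-value is below alpha (default 0.05).

Calls across strains are compared substrate-by-substrate (gains/losses per
nutrient category) and summarized by PCA on the centered binary call
matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import signal, stats

from trn_adapt.errors import DegenerateStatisticError, InvalidSpecError

logger = logging.getLogger(__name__)

CATEGORIES = ("C", "N", "S", "P", "control")


@dataclass
class PlateKinetics:
    """Per-well opacity time series plus well metadata.

    ``wells`` is indexed by well id with columns substrate, category
    (C/N/S/P/control) and is_control; ``signal`` is wells x timepoints with
    the same well index; ``timepoints`` are hours, strictly increasing.
    """

    wells: pd.DataFrame
    signal: pd.DataFrame
    timepoints: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if not (np.diff(self.timepoints) > 0).all():
            raise InvalidSpecError("timepoints must be strictly increasing")
        if int(self.wells["is_control"].sum()) < 2:
            raise InvalidSpecError("need >= 2 negative-control wells")
        if not np.isfinite(self.signal.to_numpy(dtype=float)).all():
            raise InvalidSpecError("signal must be finite")
        if not self.signal.index.equals(self.wells.index):
            raise InvalidSpecError("signal rows must match well metadata index")

    @property
    def control_ids(self) -> list:
        return list(self.wells.index[self.wells["is_control"].astype(bool)])

    @property
    def tested_ids(self) -> list:
        return list(self.wells.index[~self.wells["is_control"].astype(bool)])

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateKinetics":
        """Read the plate CSV dialect: ``well,substrate,category,is_control,<hours...>``."""
        df = pd.read_csv(path)
        meta = df[["well", "substrate", "category", "is_control"]].set_index("well")
        meta["is_control"] = meta["is_control"].astype(bool)
        time_cols = [c for c in df.columns if c not in ("well", "substrate", "category", "is_control")]
        sig = df.set_index("well")[time_cols].astype(float)
        return cls(wells=meta, signal=sig, timepoints=np.array([float(c) for c in time_cols]))

    def to_csv(self, path: str | Path) -> None:
        out = self.wells.copy()
        sig = self.signal.copy()
        sig.columns = [format(t, "g") for t in self.timepoints]
        pd.concat([out, sig], axis=1).rename_axis("well").to_csv(path)


def smooth_signal(trace: np.ndarray, window: int = 50, degree: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing of kinetic traces (time on the last axis).

    Even window lengths are rounded up to the next odd integer (the
    classical filter needs a symmetric window); boundaries use the filter's
    polynomial fit over the edge window.  A 2-D input smooths every row.
    """
    trace = np.asarray(trace, dtype=float)
    if window % 2 == 0:
        logger.info("Savitzky-Golay window %d is even; using %d", window, window + 1)
        window += 1
    if degree >= window:
        raise InvalidSpecError("polynomial degree must be smaller than the window")
    if trace.shape[-1] <= window:
        raise InvalidSpecError(
            f"trace of length {trace.shape[-1]} is shorter than window {window}"
        )
    return signal.savgol_filter(trace, window_length=window, polyorder=degree,
                                mode="interp", axis=-1)


def max_signal(trace: np.ndarray) -> float:
    """Maximum of a (smoothed) trace."""
    return float(np.max(np.asarray(trace, dtype=float)))


def growth_calls(
    plate: PlateKinetics,
    alpha: float = 0.05,
    window: int = 50,
    degree: int = 3,
    method: str = "z",
) -> pd.DataFrame:
    """One-sided z-test of each well's max smoothed signal vs negative controls.

    Control mean and sd (n-1 denominator) come from the smoothed maxima of
    the negative-control wells.  For each tested well, z = (s - mu)/sigma,
    p = upper normal tail, Bonferroni-adjusted by the number of tested
    wells on this plate; call = 1 iff adjusted p < alpha.

    The default ``method="z"`` treats the control sd as known.  With few
    control wells that sd estimate is noisy and the normal tail is
    anti-conservative at Bonferroni-scale thresholds; ``method="t"``
    instead uses the prediction-interval t statistic
    ``(s - mu) / (sigma * sqrt(1 + 1/n_controls))`` with n_controls - 1
    degrees of freedom, which gives calibrated p-values at any control
    count.
    """
    if method not in ("z", "t"):
        raise InvalidSpecError(f"unknown method {method!r}")
    smoothed = smooth_signal(plate.signal.to_numpy(dtype=float), window, degree)
    maxima = dict(zip(plate.signal.index, smoothed.max(axis=1)))
    ctrl = np.array([maxima[w] for w in plate.control_ids])
    if ctrl.size < 2:
        raise InvalidSpecError("need >= 2 negative-control wells")
    mu, sd = ctrl.mean(), ctrl.std(ddof=1)
    # tolerance absorbs float jitter from the boundary polynomial fits
    if sd <= 1e-9 * max(1.0, abs(mu)):
        raise DegenerateStatisticError("negative-control maxima have zero variance")
    tested = plate.tested_ids
    rows = []
    for w in tested:
        z = (maxima[w] - mu) / sd
        if method == "z":
            p = float(stats.norm.sf(z))
        else:
            t = z / np.sqrt(1.0 + 1.0 / ctrl.size)
            p = float(stats.t.sf(t, df=ctrl.size - 1))
        p_adj = min(1.0, p * len(tested))
        rows.append(
            {
                "well": w,
                "substrate": plate.wells.loc[w, "substrate"],
                "category": plate.wells.loc[w, "category"],
                "max_signal": maxima[w],
                "z": z,
                "pvalue": p,
                "p_adjusted": p_adj,
                "call": int(p_adj < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("well")


@dataclass
class GrowthCallMatrix:
    """Binary strains x conditions growth calls with per-cell adjusted p-values."""

    calls: pd.DataFrame
    p_adjusted: pd.DataFrame
    conditions: pd.DataFrame  # indexed by condition: substrate, category

    @classmethod
    def from_plates(cls, plates_by_strain: dict, alpha: float = 0.05,
                    window: int = 50, degree: int = 3) -> "GrowthCallMatrix":
        calls, padj, cond = {}, {}, None
        for strain, plate in plates_by_strain.items():
            res = growth_calls(plate, alpha=alpha, window=window, degree=degree)
            res = res.set_index("substrate")
            calls[strain] = res["call"]
            padj[strain] = res["p_adjusted"]
            if cond is None:
                cond = res[["category"]].copy()
        return cls(
            calls=pd.DataFrame(calls).T,
            p_adjusted=pd.DataFrame(padj).T,
            conditions=cond,
        )


def compare_calls(
    calls_a: pd.Series, calls_b: pd.Series, conditions: pd.DataFrame,
    category: str | None = None,
) -> dict:
    """Gains and losses of growth capability going from strain a to strain b.

    Returns the gained (0 -> 1) and lost (1 -> 0) condition lists plus, for
    each nutrient category (or only ``category`` if given), the loss
    percentage: 100 * |lost in category| / |grown-by-a in category|.
    """
    shared = calls_a.index.intersection(calls_b.index)
    if len(shared) == 0:
        raise InvalidSpecError("no shared conditions between the call vectors")
    a = calls_a.loc[shared].astype(int)
    b = calls_b.loc[shared].astype(int)
    gained = list(shared[(a == 0) & (b == 1)])
    lost = list(shared[(a == 1) & (b == 0)])
    cats = [category] if category else sorted(set(conditions.loc[shared, "category"]) - {"control"})
    loss_pct = {}
    for cat in cats:
        in_cat = set(shared[conditions.loc[shared, "category"] == cat])
        grown_a = [c for c in shared if c in in_cat and a[c] == 1]
        lost_cat = [c for c in lost if c in in_cat]
        loss_pct[cat] = 100.0 * len(lost_cat) / len(grown_a) if grown_a else np.nan
    return {"gained": gained, "lost": lost, "loss_percent_by_category": loss_pct}


def pca_binary(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a binary strains x conditions call matrix.

    Conditions (columns) are mean-centered but not scaled; zero-variance
    conditions are dropped with a warning; the SVD gives strain scores,
    condition loadings, and explained-variance fractions in descending
    order.
    """
    if calls.shape[0] < 3:
        raise InvalidSpecError("need >= 3 strains for PCA")
    variable = calls.columns[calls.std(axis=0) > 0]
    dropped = set(calls.columns) - set(variable)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance conditions", stacklevel=2)
    if len(variable) < 2:
        raise InvalidSpecError("need >= 2 conditions with variance")
    x = calls[variable].to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var_frac = s**2 / np.sum(s**2)
    n_pc = len(s)
    pcs = [f"PC{i + 1}" for i in range(n_pc)]
    scores = pd.DataFrame(u * s, index=calls.index, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=variable, columns=pcs)
    return scores, loadings, var_frac
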