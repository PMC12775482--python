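"""The substrate score calculus.

Selectivity of a substrate for a target protease is its cleavage score minus
the mean score across the other panel proteases. Raw fluorogenic screen
kinetics reduce to per-substrate cleavage efficiencies in [0, 1] (0 for
non-cleaved, 1 for the best-cleaved substrate). Per-protease cleavage
thresholds T_m — the predicted-score operating point that best separates
cleaved from non-cleaved calls — calibrate predicted scores into corrected
efficiencies (0 below threshold, scaled to a columnwise max of 1 above) and
corrected selectivities bounded in [-1, 1]. A quadrant assignment at fixed
efficiency/selectivity cuts classifies substrates for design triage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("cleavekit")


# ---------------------------------------------------------------------------
# Selectivity (panel-relative score)
# ---------------------------------------------------------------------------


def selectivity_score(profile: np.ndarray, target: int, axis: int = -1) -> np.ndarray:
    """Target score minus the mean of the other M-1 panel scores.

    ``profile`` may be a single (M,) vector or an (n, M) matrix.
    """
    profile = np.asarray(profile, dtype=float)
    M = profile.shape[axis]
    if M < 2:
        raise ValueError("selectivity requires a panel of at least 2 proteases")
    others = np.delete(profile, target, axis=axis)
    return np.take(profile, target, axis=axis) - others.mean(axis=axis)


# ---------------------------------------------------------------------------
# Screen kinetics -> efficiencies
# ---------------------------------------------------------------------------


@dataclass
class ScreenMeasurement:
    """Fluorescence kinetics for one substrate-protease-replicate."""

    substrate: str
    protease: str
    replicate: str
    time_min: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if not np.all(np.diff(self.time_min) > 0):
            raise ValueError("time points must be strictly increasing")
        if (self.fluorescence < 0).any():
            raise ValueError("fluorescence must be non-negative")

    def fold_change(self) -> float:
        """Endpoint over initial fluorescence."""
        f0 = self.fluorescence[0]
        if f0 <= 0:
            raise ValueError("initial fluorescence must be positive for fold change")
        return float(self.fluorescence[-1] / f0)

    def rate(self) -> float:
        """Least-squares slope of fluorescence vs time (units/min)."""
        t, f = self.time_min, self.fluorescence
        t0 = t - t.mean()
        return float((t0 * (f - f.mean())).sum() / (t0 * t0).sum())


def read_kinetics(path) -> pd.DataFrame:
    """Long-format kinetics CSV: substrate,protease,replicate,time_min,fluorescence."""
    df = pd.read_csv(path)
    required = {"substrate", "protease", "replicate", "time_min", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: kinetics CSV missing columns {sorted(missing)}")
    return df


def reduce_kinetics(df: pd.DataFrame, mode: str = "endpoint_fold_change") -> pd.DataFrame:
    """Replicate-averaged signal per (substrate, protease).

    ``mode='endpoint_fold_change'`` uses endpoint/initial fluorescence;
    ``mode='rate'`` uses the least-squares slope. Replicates are averaged
    after reduction.
    """
    rows = []
    for (sub, prot, rep), grp in df.groupby(["substrate", "protease", "replicate"]):
        grp = grp.sort_values("time_min")
        meas = ScreenMeasurement(sub, prot, str(rep),
                                 grp["time_min"].to_numpy(),
                                 grp["fluorescence"].to_numpy())
        value = meas.fold_change() if mode == "endpoint_fold_change" else meas.rate()
        rows.append({"substrate": sub, "protease": prot, "replicate": rep,
                     "signal": value})
    per_rep = pd.DataFrame(rows)
    return (per_rep.groupby(["substrate", "protease"], as_index=False)["signal"]
            .mean())


def call_cleaved(
    signals: pd.DataFrame,
    blank_protease: str | None = None,
    fold_change_floor: float = 1.2,
) -> pd.DataFrame:
    """Binary cleavage calls from replicate-averaged signals.

    If ``blank_protease`` names no-enzyme control rows, the cutoff is their
    mean + 3 sd per substrate pool; otherwise a fixed fold-change floor is
    used.
    """
    signals = signals.copy()
    if blank_protease is not None and (signals["protease"] == blank_protease).any():
        blanks = signals.loc[signals["protease"] == blank_protease, "signal"]
        cutoff = float(blanks.mean() + 3 * blanks.std(ddof=0))
        signals = signals[signals["protease"] != blank_protease]
    else:
        cutoff = fold_change_floor
    signals["cleaved"] = signals["signal"] > cutoff
    logger.info("cleavage calls: cutoff %.3f, %d/%d cleaved",
                cutoff, int(signals["cleaved"].sum()), len(signals))
    return signals


def efficiency_from_screen(
    signals: pd.DataFrame,
    fc_min_mode: str = "noncleaved_mean",
) -> pd.DataFrame:
    """Transform cleavage calls + signals into efficiencies in [0, 1].

    Per protease: non-cleaved substrates score 0; the substrate with the
    highest signal scores exactly 1; other cleaved substrates score
    ``FC_x / (FC_max - FC_minbar)`` clipped to [0, 1], where FC_minbar is the
    mean signal of non-cleaved substrates (``fc_min_mode='zero'`` recovers the
    simpler FC_x / FC_max reading).
    """
    if not {"substrate", "protease", "signal", "cleaved"} <= set(signals.columns):
        raise ValueError("signals must have substrate/protease/signal/cleaved columns")
    out = []
    for prot, grp in signals.groupby("protease"):
        grp = grp.copy()
        cleaved = grp["cleaved"].to_numpy()
        sig = grp["signal"].to_numpy(dtype=float)
        eff = np.zeros(len(grp))
        if not cleaved.any():
            warnings.warn(f"no cleaved substrates for {prot}: all efficiencies 0")
        else:
            fc_max = sig[cleaved].max()
            if fc_min_mode == "noncleaved_mean" and (~cleaved).any():
                fc_min = sig[~cleaved].mean()
            else:
                fc_min = 0.0
            denom = fc_max - fc_min
            if denom <= 0:
                denom = fc_max if fc_max > 0 else 1.0
            eff = np.where(cleaved, np.clip(sig / denom, 0.0, 1.0), 0.0)
            eff[np.flatnonzero(cleaved)[np.argmax(sig[cleaved])]] = 1.0
        grp["efficiency"] = eff
        out.append(grp)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Threshold calibration and classification
# ---------------------------------------------------------------------------


@dataclass
class ThresholdTable:
    """Per-protease cleavage thresholds; proteases without screen labels get
    the mean of the fitted thresholds, flagged as imputed."""

    thresholds: dict[str, float]
    imputed: dict[str, bool]
    youden_j: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "protease": list(self.thresholds),
            "threshold": [self.thresholds[p] for p in self.thresholds],
            "imputed": [self.imputed[p] for p in self.thresholds],
            "youden_j": [self.youden_j.get(p, np.nan) for p in self.thresholds],
        })

    def vector(self, panel: list[str]) -> np.ndarray:
        return np.array([self.thresholds[p] for p in panel])


def _best_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Exhaustive scan of candidate cuts (midpoints between adjacent sorted
    scores) maximizing Youden's J for the rule ``score > T``; ties resolve to
    the midpoint of the optimal candidate interval."""
    order = np.argsort(scores)
    s = scores[order]
    uniq = np.unique(s)
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_j, best_ts = -np.inf, []
    for t in candidates:
        pred = scores > t
        tp = (pred & labels).sum()
        fp = (pred & ~labels).sum()
        j = tp / n_pos - fp / n_neg
        if j > best_j + 1e-12:
            best_j, best_ts = j, [t]
        elif abs(j - best_j) <= 1e-12:
            best_ts.append(t)
    return float(np.median(best_ts)), float(best_j)


def fit_cleavage_thresholds(
    zhat: pd.DataFrame | np.ndarray,
    cleaved: pd.DataFrame | np.ndarray,
    panel: list[str] | None = None,
) -> ThresholdTable:
    """Per-protease predicted-score cut best separating cleaved from
    non-cleaved (maximum Youden's J along the ROC). Proteases with single-class
    or missing labels receive the mean of the fitted thresholds, flagged
    imputed.

    ``zhat``/``cleaved`` are (n_substrates, M); NaNs in ``cleaved`` mark
    unscreened pairs.
    """
    if isinstance(zhat, pd.DataFrame):
        panel = list(zhat.columns)
        zhat = zhat.to_numpy(dtype=float)
    if isinstance(cleaved, pd.DataFrame):
        cleaved = cleaved.to_numpy(dtype=float)
    zhat = np.asarray(zhat, dtype=float)
    cleaved = np.asarray(cleaved, dtype=float)
    if panel is None:
        panel = [f"protease{j}" for j in range(zhat.shape[1])]
    thresholds: dict[str, float] = {}
    imputed: dict[str, bool] = {}
    youden: dict[str, float] = {}
    fitted = []
    for j, name in enumerate(panel):
        mask = ~np.isnan(cleaved[:, j])
        labels = cleaved[mask, j].astype(bool)
        if mask.sum() == 0 or labels.all() or not labels.any():
            if mask.sum() > 0:
                warnings.warn(f"{name}: single-class labels; threshold imputed")
            imputed[name] = True
            continue
        t, jstat = _best_threshold(zhat[mask, j], labels)
        if jstat < 0.25:
            warnings.warn(f"{name}: labels uninformative (Youden J={jstat:.3f}); "
                          "threshold is low-confidence")
        thresholds[name] = t
        youden[name] = jstat
        imputed[name] = False
        fitted.append(t)
    if not fitted:
        raise ValueError("no protease has both cleaved and non-cleaved labels")
    mean_fitted = float(np.mean(fitted))
    for name in panel:
        if imputed.get(name, True):
            imputed[name] = True
            thresholds[name] = mean_fitted
    thresholds = {name: thresholds[name] for name in panel}
    logger.info("fitted %d thresholds (mean %.3f), imputed %d",
                len(fitted), mean_fitted, sum(imputed.values()))
    return ThresholdTable(thresholds=thresholds, imputed=imputed, youden_j=youden)


def classify_cleaved(
    zhat: np.ndarray, thresholds: np.ndarray, labels: np.ndarray | None = None
) -> dict:
    """Cleaved call = (Ẑ > T_m), strict. With labels, also the 2x2-table
    metrics (sensitivity, specificity, accuracy)."""
    zhat = np.asarray(zhat, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    calls = zhat > thresholds
    out = {"calls": calls}
    if labels is not None:
        labels = np.asarray(labels).astype(bool)
        tp = (calls & labels).sum()
        tn = (~calls & ~labels).sum()
        fn = (~calls & labels).sum()
        fp = (calls & ~labels).sum()
        out["sensitivity"] = tp / (tp + fn) if (tp + fn) else np.nan
        out["specificity"] = tn / (tn + fp) if (tn + fp) else np.nan
        out["accuracy"] = (tp + tn) / calls.size
    return out


# ---------------------------------------------------------------------------
# Corrected efficiency / selectivity and quadrants
# ---------------------------------------------------------------------------


def corrected_efficiency(zhat: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Threshold-corrected efficiency per (substrate, protease):

    Ê = (Ẑ - T_m) / max_substrates(Ẑ - T_m) when Ẑ > T_m, else 0. The
    columnwise max of Ê is 1 for any column with at least one cleaved
    substrate.
    """
    zhat = np.asarray(zhat, dtype=float)
    if zhat.size == 0:
        raise ValueError("empty score matrix")
    thresholds = np.asarray(thresholds, dtype=float)
    adj = zhat - thresholds
    cleaved = adj > 0
    denom = np.where(cleaved, adj, -np.inf).max(axis=0)
    safe = np.where(np.isfinite(denom) & (denom > 0), denom, 1.0)
    return np.where(cleaved, adj / safe, 0.0)


def corrected_selectivity(efficiency: np.ndarray, target: int) -> np.ndarray:
    """Corrected efficiency of the target minus the mean over the others;
    bounded in [-1, 1] since efficiencies live in [0, 1]."""
    return selectivity_score(efficiency, target)


QUADRANTS = {
    (False, False): "low-efficiency/low-selectivity",
    (False, True): "low-efficiency/high-selectivity",
    (True, False): "high-efficiency/low-selectivity",
    (True, True): "high-efficiency/high-selectivity",
}


def quadrant_assign(efficiency, selectivity, e_cut: float = 0.4, s_cut: float = 2.4):
    """Quadrant label(s) from strict cuts E > e_cut and S > s_cut."""
    e = np.asarray(efficiency, dtype=float)
    s = np.asarray(selectivity, dtype=float)
    if e.ndim == 0:
        return QUADRANTS[(bool(e > e_cut), bool(s > s_cut))]
    return [QUADRANTS[(bool(ei > e_cut), bool(si > s_cut))] for ei, si in zip(e, s)]
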