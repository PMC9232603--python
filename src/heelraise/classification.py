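"""Eversion/inversion posture classification on the (MPP, roll) plane.

Each repetition contributes one point per phase — its mean medial partial
pressure and mean roll angle.  Eversion raises sit higher in MPP and at
more positive (medial) roll than inversion raises by the same subject, but
habitual medial loading differs enough between subjects that a single
vertical MPP line over pooled data can fail; either a per-subject MPP
threshold (personal calibration) or a pooled two-dimensional linear
boundary that also uses the roll axis separates the classes.

Two boundary kinds are provided: ``mpp_threshold`` (midpoint between the
class MPP means) and ``linear_2d`` (two-class linear discriminant with
equal priors on MPP and roll).  Ties on the boundary are labeled IV — the
conservative call in a rehabilitation setting, where a false "improper
posture" flag is safer than a false "proper".

``fit_linear_relation`` quantifies how well a raw accelerometer axis tracks
the reference orientation angle (ordinary least squares, R²), the basis for
using the insole accelerometer as an orientation surrogate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import CalibrationError, FitError, ParameterError

EV, IV = "EV", "IV"


def variant_orientation(variant: str) -> str:
    """Map a heel-raise variant label (e.g. ``SL-IV``) to EV/IV."""
    if variant.endswith(EV):
        return EV
    if variant.endswith(IV):
        return IV
    raise ParameterError(f"cannot infer orientation from variant '{variant}'")


def event_points(
    features: pd.DataFrame,
    phases: tuple[str, ...] = ("rise", "hold", "drop"),
) -> pd.DataFrame:
    """One (MPP, roll) point per event × selected phase.

    Keeps any grouping columns present (``subject``, ``variant``,
    ``label``); rows with undefined MPP are omitted with a warning.
    """
    sel = features[features["phase"].isin(phases)].copy()
    undef = sel["mean_mpp_pct"].isna()
    if undef.any():
        warnings.warn(
            f"omitting {int(undef.sum())} points with undefined MPP", stacklevel=2
        )
        sel = sel[~undef]
    cols = ["event_index", "phase", "mean_mpp_pct", "mean_roll_deg"]
    extra = [c for c in ("subject", "variant", "label") if c in sel.columns]
    out = sel[cols + extra].rename(
        columns={"mean_mpp_pct": "mpp", "mean_roll_deg": "roll"}
    )
    if "label" not in out.columns and "variant" in out.columns:
        out["label"] = out["variant"].map(variant_orientation)
    return out.reset_index(drop=True)


@dataclass
class OrientationBoundary:
    """A fitted EV/IV decision boundary.

    ``decision_value`` is positive on the eversion side; exactly zero is a
    tie and resolves to IV.
    """

    kind: str  # "mpp_threshold" | "linear_2d"
    threshold_pct: float | None = None
    weight_mpp: float = 0.0
    weight_roll: float = 0.0
    offset: float = 0.0
    training: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("mpp_threshold", "linear_2d"):
            raise ParameterError(f"unknown boundary kind '{self.kind}'")
        if self.kind == "linear_2d" and self.weight_mpp == 0 and self.weight_roll == 0:
            raise ParameterError("linear_2d weights must not both be zero")

    def decision_value(self, mpp_pct, roll_deg) -> np.ndarray:
        mpp_pct = np.asarray(mpp_pct, dtype=float)
        roll_deg = np.asarray(roll_deg, dtype=float)
        if self.kind == "mpp_threshold":
            return mpp_pct - self.threshold_pct
        return self.weight_mpp * mpp_pct + self.weight_roll * roll_deg + self.offset

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "OrientationBoundary":
        return cls(**json.loads(text))


def fit_boundary(points: pd.DataFrame, kind: str = "linear_2d") -> OrientationBoundary:
    """Fit an EV/IV boundary from labeled (MPP, roll) points.

    ``mpp_threshold``: midpoint between the two class MPP means (needs ≥ 1
    point per class).  ``linear_2d``: linear discriminant with equal priors
    on (MPP, roll), needs ≥ 2 points per class.
    """
    for col in ("mpp", "roll", "label"):
        if col not in points.columns:
            raise ParameterError(f"points missing column '{col}'")
    ev = points[points["label"] == EV]
    iv = points[points["label"] == IV]
    if len(ev) == 0 or len(iv) == 0:
        raise CalibrationError("need at least one point per class")
    training = {
        "n_points": int(len(ev) + len(iv)),
        "n_ev": int(len(ev)),
        "n_iv": int(len(iv)),
        "subjects": sorted(points["subject"].unique().tolist())
        if "subject" in points.columns
        else None,
    }
    if kind == "mpp_threshold":
        thr = 0.5 * (float(ev["mpp"].mean()) + float(iv["mpp"].mean()))
        return OrientationBoundary(kind=kind, threshold_pct=thr, training=training)
    if kind != "linear_2d":
        raise ParameterError(f"unknown boundary kind '{kind}'")
    if len(ev) < 2 or len(iv) < 2:
        raise CalibrationError("linear_2d needs at least two points per class")
    X = points[["mpp", "roll"]].to_numpy(dtype=float)
    y = (points["label"] == EV).to_numpy(dtype=int)
    lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    lda.fit(X, y)
    # orient the decision value so EV (class 1) is positive
    w = lda.coef_[0]
    b = float(lda.intercept_[0])
    return OrientationBoundary(
        kind=kind,
        weight_mpp=float(w[0]),
        weight_roll=float(w[1]),
        offset=b,
        training=training,
    )


def classify(points: pd.DataFrame, boundary: OrientationBoundary) -> pd.DataFrame:
    """Label each point and each event (majority over its phases).

    Adds ``pred_label`` per point and ``pred_event_label`` (shared across
    the event's rows).  Boundary ties and majority ties resolve to IV.
    """
    out = points.copy()
    score = boundary.decision_value(out["mpp"], out["roll"])
    out["decision_value"] = score
    out["pred_label"] = np.where(score > 0, EV, IV)

    group_cols = [c for c in ("subject", "variant") if c in out.columns]
    group_cols.append("event_index")

    def majority(labels: pd.Series) -> str:
        n_ev = int((labels == EV).sum())
        n_iv = int((labels == IV).sum())
        return EV if n_ev > n_iv else IV

    event_label = out.groupby(group_cols)["pred_label"].transform(majority)
    out["pred_event_label"] = event_label
    return out


def event_accuracy(classified: pd.DataFrame) -> float:
    """Fraction of events whose majority label matches the true label."""
    group_cols = [c for c in ("subject", "variant") if c in classified.columns]
    group_cols.append("event_index")
    per_event = classified.groupby(group_cols)[["label", "pred_event_label"]].first()
    return float((per_event["label"] == per_event["pred_event_label"]).mean())


@dataclass
class RegressionFit:
    """Ordinary-least-squares fit of an angle trace on an accel trace."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ParameterError("r_squared must lie in [0, 1]")


def fit_linear_relation(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """OLS of ``y`` (angle) on ``x`` (acceleration): slope, intercept, R².

    Zero variance in ``x`` is a fit error; a constant ``y`` (zero total sum
    of squares) is degenerate and reported with a warning as R² = 1 (the
    constant is reproduced exactly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ParameterError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("inputs must be finite")
    if np.ptp(x) == 0.0:
        raise FitError("zero variance in x")
    if np.ptp(y) == 0.0:
        warnings.warn("zero variance in y; degenerate regression", stacklevel=2)
        return RegressionFit(slope=0.0, intercept=float(y[0]), r_squared=1.0, n=len(x))
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )
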