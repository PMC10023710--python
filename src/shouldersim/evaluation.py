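"""Kinematic/kinetic evaluation: accuracy, repeatability, reliability.

The pipeline mirrors the rig's data analysis: the scored segment of every
trial is resampled onto a 1-degree grid of the profiled DOF's setpoint;
accuracy is the across-trial mean deviation (its maximum over the grid)
and the RMSE between achieved and target angles; repeatability is the
maximum and grid-averaged standard deviation across repeats; reliability
is the intraclass correlation coefficient ICC(A,1) -- single-measurement,
absolute-agreement, two-way model -- of translations and individual muscle
forces across repeats, with 95% confidence intervals and the conventional
interpretation bands (< 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good,
>= 0.9 excellent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .simulate import TrialTrace

__all__ = [
    "resample_by_angle",
    "accuracy_metrics",
    "repeatability_sd",
    "icc_a1",
    "interpret_icc",
    "IccResult",
    "MetricsReport",
    "evaluate_campaign",
]

#: profiled DOF used as the grid variable, per protocol
GRID_DOF = {
    "abduction": "abd",
    "flexion": "fe",
    "extension": "fe",
    "internal_rotation": "ir",
    "external_rotation": "ir",
    "extension_internal_rotation": "fe",
}

DOF_COLS = {"abd": ("sp_abd", "pv_abd"), "fe": ("sp_fe", "pv_fe"), "ir": ("sp_ir", "pv_ir")}
TRANSLATION_COLS = ("ap_mm", "si_mm", "ml_mm")
FORCE_COLS = ("f_md", "f_ad", "f_pd", "f_ssc", "f_isp_tm", "f_ssp")
PLANAR = ("abduction", "flexion", "extension", "internal_rotation", "external_rotation")


def resample_by_angle(
    trace: TrialTrace,
    dof: str | None = None,
    increment_deg: float = 1.0,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Resample the scored segment onto the integer-degree setpoint grid.

    ``dof`` defaults to the protocol's profiled DOF.  All value columns
    are linearly interpolated against the (monotone) setpoint of that DOF;
    the returned frame is indexed by grid angle (inclusive of both ends,
    ascending or descending with the ramp).
    """
    dof = dof if dof is not None else GRID_DOF[trace.protocol]
    sp_col = DOF_COLS[dof][0]
    seg = trace.scored()
    if len(seg) < 2:
        raise ValueError("scored segment is empty")
    sp = seg[sp_col].to_numpy()
    dsp = np.diff(sp)
    sign = 1.0 if sp[-1] >= sp[0] else -1.0
    if np.any(sign * dsp < -1e-9):
        raise ValueError(f"setpoint {sp_col} not monotone over the scored segment")
    lo, hi = (sp[0], sp[-1]) if sign > 0 else (sp[-1], sp[0])
    grid = np.arange(np.ceil(lo - 1e-9), np.floor(hi + 1e-9) + 0.5, increment_deg)
    if sign < 0:
        grid = grid[::-1]
    cols = list(columns) if columns is not None else [
        c for c in seg.columns if c not in ("time_s",)
    ]
    x = sign * sp
    out = {}
    for c in cols:
        out[c] = np.interp(sign * grid, x, seg[c].to_numpy())
    df = pd.DataFrame(out, index=pd.Index(grid, name=f"{dof}_deg"))
    return df


def accuracy_metrics(
    resampled: Sequence[pd.DataFrame], dof: str
) -> tuple[float, float]:
    """(max |across-trial mean deviation|, RMSE) for one DOF, degrees.

    The mean deviation at each grid point is the mean over trials of
    (achieved - target); its largest magnitude over the grid is reported.
    The RMSE pools squared deviations over grid points and trials.
    """
    if not len(resampled):
        raise ValueError("no traces given")
    sp_col, pv_col = DOF_COLS[dof]
    dev = np.stack([(df[pv_col] - df[sp_col]).to_numpy() for df in resampled])
    mean_dev = dev.mean(axis=0)
    return float(np.abs(mean_dev).max()), float(np.sqrt(np.mean(dev**2)))


def repeatability_sd(
    resampled: Sequence[pd.DataFrame], dof: str
) -> tuple[float, float]:
    """(max SD, grid-averaged SD) of the achieved angle across repeats."""
    if len(resampled) < 2:
        raise ValueError("need at least 2 repeats")
    pv_col = DOF_COLS[dof][1]
    pv = np.stack([df[pv_col].to_numpy() for df in resampled])
    sd = pv.std(axis=0, ddof=1)
    return float(sd.max()), float(sd.mean())


# ---------------------------------------------------------------------------
# ICC(A,1)


@dataclass(frozen=True)
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    degenerate: bool = False

    @property
    def category(self) -> str:
        return interpret_icc(self.estimate)


def icc_a1(matrix: np.ndarray, ci: float = 0.95) -> IccResult:
    """ICC(A,1): single-measurement, absolute-agreement, two-way model.

    ``matrix`` is n targets (rows) x k raters/repeats (columns).  The
    estimate is (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)) from
    the two-way ANOVA mean squares; the confidence interval is the
    F-based absolute-agreement interval with Satterthwaite degrees of
    freedom (McGraw & Wong 1996).  A matrix with zero variance everywhere
    returns estimate 1 with the ``degenerate`` flag set.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D")
    n, k = X.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 targets and 2 repeats")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix entries must be finite")

    grand = X.mean()
    rows = X.mean(axis=1)
    cols = X.mean(axis=0)
    msr = k * np.sum((rows - grand) ** 2) / (n - 1)
    msc = n * np.sum((cols - grand) ** 2) / (k - 1)
    resid = X - rows[:, None] - cols[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or (msr < 1e-30 and msc < 1e-30 and mse < 1e-30):
        return IccResult(1.0, np.nan, np.nan, degenerate=True)
    est = (msr - mse) / denom

    alpha = 1.0 - ci
    if mse < 1e-30:
        return IccResult(float(est), np.nan, np.nan, degenerate=True)
    a = (k * est) / (n * (1.0 - est)) if est < 1.0 else np.inf
    b = 1.0 + (k * est * (n - 1.0)) / (n * (1.0 - est)) if est < 1.0 else np.inf
    if not np.isfinite(a):
        return IccResult(float(est), np.nan, np.nan, degenerate=True)
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    v = v_num / v_den
    f_l = f_dist.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = f_dist.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return IccResult(float(est), float(lower), float(upper))


def interpret_icc(value: float) -> str:
    """Conventional reliability bands for an ICC estimate."""
    if not (-1.0 - 1e-12 <= value <= 1.0 + 1e-12):
        raise ValueError(f"ICC must lie in [-1, 1], got {value}")
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.9:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# Campaign-level report


@dataclass
class MetricsReport:
    """Full evaluation: accuracy/repeatability per protocol x DOF and
    ICC per muscle / translation axis."""

    accuracy: pd.DataFrame  # protocol, dof, max_mean_dev_deg, rmse_deg
    repeatability: pd.DataFrame  # protocol, dof, max_sd_deg, avg_sd_deg
    icc_forces: pd.DataFrame  # protocol, muscle, estimate, ci_low, ci_high, category
    icc_translations: pd.DataFrame  # protocol, axis, estimate, ...
    pooling: str = "pooled"

    def summary(self) -> dict:
        out = {
            "max_mean_deviation_deg": float(self.accuracy.max_mean_dev_deg.max()),
            "max_rmse_deg": float(self.accuracy.rmse_deg.max()),
            "max_sd_deg": float(self.repeatability.max_sd_deg.max()),
            "max_avg_sd_deg": float(self.repeatability.avg_sd_deg.max()),
            "n_force_icc": int(len(self.icc_forces)),
            "n_force_icc_ci_above_0.90": int((self.icc_forces.ci_low > 0.90).sum()),
            "n_translation_icc": int(len(self.icc_translations)),
            "n_translation_icc_ci_above_0.90": int(
                (self.icc_translations.ci_low > 0.90).sum()
            ),
        }
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "pooling": self.pooling,
            "summary": self.summary(),
            "accuracy": self.accuracy.to_dict(orient="records"),
            "repeatability": self.repeatability.to_dict(orient="records"),
            "icc_forces": self.icc_forces.to_dict(orient="records"),
            "icc_translations": self.icc_translations.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        rows = []
        for _, r in self.accuracy.iterrows():
            rows.append(
                dict(kind="accuracy", protocol=r.protocol, item=r.dof,
                     max_mean_dev_deg=r.max_mean_dev_deg, rmse_deg=r.rmse_deg)
            )
        for _, r in self.repeatability.iterrows():
            rows.append(
                dict(kind="repeatability", protocol=r.protocol, item=r.dof,
                     max_sd_deg=r.max_sd_deg, avg_sd_deg=r.avg_sd_deg)
            )
        for kind, df, item in (
            ("icc_force", self.icc_forces, "muscle"),
            ("icc_translation", self.icc_translations, "axis"),
        ):
            for _, r in df.iterrows():
                rows.append(
                    dict(kind=kind, protocol=r.protocol, item=r[item],
                         estimate=r.estimate, ci_low=r.ci_low, ci_high=r.ci_high,
                         category=r.category)
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def _group_traces(traces: Iterable[TrialTrace]):
    by_protocol: dict[str, list[TrialTrace]] = {}
    for t in traces:
        by_protocol.setdefault(t.protocol, []).append(t)
    return by_protocol


def evaluate_campaign(
    traces: Sequence[TrialTrace],
    *,
    pooling: str = "pooled",
    increment_deg: float = 1.0,
) -> MetricsReport:
    """Evaluate a full simulation campaign.

    Accuracy pools all trials of a protocol (specimens x repeats).
    Repeatability is computed per specimen across its repeats; the
    reported numbers are the maxima over specimens.  ICC matrices have
    rows = grid points (stacked across specimens when ``pooling`` is
    ``"pooled"``, the default; per-specimen medians when
    ``"per_specimen"``) and columns = repeats.
    """
    if pooling not in ("pooled", "per_specimen"):
        raise ValueError("pooling must be 'pooled' or 'per_specimen'")
    acc_rows, rep_rows, icc_f_rows, icc_t_rows = [], [], [], []
    for protocol, group in _group_traces(traces).items():
        resampled = {
            (t.specimen_id, t.repeat): resample_by_angle(t, increment_deg=increment_deg)
            for t in group
        }
        specimens = sorted({s for s, _ in resampled})
        repeats = sorted({r for _, r in resampled})
        all_frames = list(resampled.values())
        for dof in ("abd", "fe", "ir"):
            mmd, rmse = accuracy_metrics(all_frames, dof)
            acc_rows.append(
                dict(protocol=protocol, dof=dof, max_mean_dev_deg=mmd, rmse_deg=rmse)
            )
            max_sd = avg_sd = 0.0
            for s in specimens:
                frames = [resampled[(s, r)] for r in repeats if (s, r) in resampled]
                if len(frames) >= 2:
                    ms, as_ = repeatability_sd(frames, dof)
                    max_sd, avg_sd = max(max_sd, ms), max(avg_sd, as_)
            rep_rows.append(
                dict(protocol=protocol, dof=dof, max_sd_deg=max_sd, avg_sd_deg=avg_sd)
            )

        def icc_of(col: str) -> IccResult:
            mats = []
            for s in specimens:
                frames = [resampled[(s, r)] for r in repeats if (s, r) in resampled]
                if len(frames) < 2:
                    continue
                mats.append(np.stack([f[col].to_numpy() for f in frames], axis=1))
            if not mats:
                raise ValueError(f"not enough repeats for ICC of {col}")
            if pooling == "pooled":
                return icc_a1(np.vstack(mats))
            per = [icc_a1(m) for m in mats]
            est = float(np.median([p.estimate for p in per]))
            lo = float(np.median([p.ci_low for p in per]))
            hi = float(np.median([p.ci_high for p in per]))
            return IccResult(est, lo, hi, any(p.degenerate for p in per))

        muscle_names = ("MD", "AD", "PD", "SSC", "ISP/TM", "SSP")
        for col, m in zip(FORCE_COLS, muscle_names):
            r = icc_of(col)
            icc_f_rows.append(
                dict(protocol=protocol, muscle=m, estimate=r.estimate,
                     ci_low=r.ci_low, ci_high=r.ci_high, category=r.category)
            )
        if protocol in PLANAR:
            for col, ax in zip(TRANSLATION_COLS, ("AP", "SI", "ML")):
                r = icc_of(col)
                icc_t_rows.append(
                    dict(protocol=protocol, axis=ax, estimate=r.estimate,
                         ci_low=r.ci_low, ci_high=r.ci_high, category=r.category)
                )
    return MetricsReport(
        accuracy=pd.DataFrame(acc_rows),
        repeatability=pd.DataFrame(rep_rows),
        icc_forces=pd.DataFrame(icc_f_rows),
        icc_translations=pd.DataFrame(icc_t_rows),
        pooling=pooling,
    )
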