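"""Waveform file I/O, QC rules, derived scalar measures, cohort summaries.

The exchange format is a UTF-8 CSV with a header row and ``#key=value``
comment lines carrying metadata (subject_id, cycle_duration_s, frame_count,
and optionally age, sex, mr_icp_mmhg).  Two column dialects are accepted:

    frame,q_av_ml_s,q_csf_ml_s
    frame,arterial_ml_s,venous_ml_s,q_csf_ml_s

In the four-column dialect the net transcranial flow is computed as
arterial minus venous, and the venous-onset QC rule can be evaluated.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import WaveformParseError
from .model_core import CardiacCycleData

__all__ = [
    "SubjectRecord",
    "QC_VENOUS_FIRST",
    "QC_INDETERMINATE",
    "AGE_BANDS",
    "read_waveforms",
    "write_waveforms",
    "net_transcranial_flow",
    "qc_venous_onset",
    "csf_stroke_volume",
    "cohort_summary",
]

QC_VENOUS_FIRST = "venous_onset_precedes_arterial"
QC_INDETERMINATE = "qc_indeterminate_flat_waveform"

# Age strata, closed on both ends, ages in integer years.
AGE_BANDS = [(3, 10), (11, 20), (21, 40), (41, 60)]

_THREE_COL = ["frame", "q_av_ml_s", "q_csf_ml_s"]
_FOUR_COL = ["frame", "arterial_ml_s", "venous_ml_s", "q_csf_ml_s"]


@dataclass
class SubjectRecord:
    """One subject's cycle plus metadata and QC outcome.

    ``qc_flags`` is empty for analyzable subjects; flagged subjects are
    excluded from estimation.
    """

    subject_id: str
    cycle: CardiacCycleData
    age: int | None = None
    sex: str | None = None
    mr_icp: float | None = None
    qc_flags: list[str] = field(default_factory=list)
    arterial: np.ndarray | None = None
    venous: np.ndarray | None = None

    @property
    def analyzable(self) -> bool:
        return not self.qc_flags


def net_transcranial_flow(arterial: np.ndarray, venous: np.ndarray) -> np.ndarray:
    """Q_A-V = arterial inflow minus venous outflow, elementwise (mL/s)."""
    a = np.asarray(arterial, dtype=float)
    v = np.asarray(venous, dtype=float)
    if a.shape != v.shape:
        raise WaveformParseError(
            f"arterial and venous lengths differ: {a.shape} vs {v.shape}"
        )
    return a - v


def _cyclic_onset(signal: np.ndarray, rise_fraction: float = 0.1) -> int | None:
    """Foot of a periodic waveform: first frame, scanning cyclically from the
    global minimum, exceeding min + rise_fraction * peak-to-peak.

    Returns None for a flat waveform (zero peak-to-peak).
    """
    x = np.asarray(signal, dtype=float)
    ptp = float(x.max() - x.min())
    if ptp == 0.0:
        return None
    level = x.min() + rise_fraction * ptp
    start = int(np.argmin(x))
    n = len(x)
    for k in range(n):
        idx = (start + k) % n
        if x[idx] > level:
            return idx
    return None  # unreachable for ptp > 0


def qc_venous_onset(
    arterial: np.ndarray, venous: np.ndarray, rise_fraction: float = 0.1
) -> str | None:
    """Exclusion rule: venous outflow must not precede arterial inflow.

    The model has no active venous pumping, so a subject whose venous onset
    comes before the arterial onset cannot be represented.  Onsets are
    detected with a cyclic foot detector (10% above the waveform minimum by
    default).  On a circular axis "precedes" is taken as: the venous foot is
    nearer behind the arterial foot than ahead of it, i.e. the cyclic lag
    (venous_onset - arterial_onset) mod N is zero or exceeds N/2.

    Returns a QC flag string, or None when the subject passes.
    """
    a = np.asarray(arterial, dtype=float)
    v = np.asarray(venous, dtype=float)
    if a.shape != v.shape or len(a) < 8:
        raise WaveformParseError(
            f"waveforms must share length >= 8, got {a.shape} vs {v.shape}"
        )
    onset_a = _cyclic_onset(a, rise_fraction)
    onset_v = _cyclic_onset(v, rise_fraction)
    if onset_a is None or onset_v is None:
        return QC_INDETERMINATE
    n = len(a)
    lag = (onset_v - onset_a) % n
    if lag == 0 or lag > n / 2:
        return QC_VENOUS_FIRST
    return None


def csf_stroke_volume(
    q_csf: np.ndarray, cycle_duration: float
) -> tuple[float, float]:
    """CSF volume displaced per cardiac cycle, mL, in both directions.

    Integrates (rectangle rule, T = cycle_duration / frame_count) the
    positive lobe of Q_CSF — the caudal displacement under the convention
    that positive flow is craniocaudal — and the magnitude of the negative
    lobe (the return flow).  By near-conservation over the cycle the two are
    approximately equal.  Returns (caudal, cranial_return).
    """
    q = np.asarray(q_csf, dtype=float)
    T = cycle_duration / len(q)
    caudal = float(np.sum(np.clip(q, 0.0, None)) * T)
    cranial = float(-np.sum(np.clip(q, None, 0.0)) * T)
    return caudal, cranial


def write_waveforms(path: str | Path, record: "SubjectRecord") -> None:
    """Write a subject to the waveform CSV format (four-column dialect when
    arterial/venous traces are present, three-column otherwise)."""
    path = Path(path)
    cyc = record.cycle
    lines = [
        f"# subject_id={record.subject_id}",
        f"# cycle_duration_s={float(cyc.cycle_duration)!r}",
        f"# frame_count={cyc.frame_count}",
    ]
    if record.age is not None:
        lines.append(f"# age={record.age}")
    if record.sex is not None:
        lines.append(f"# sex={record.sex}")
    if record.mr_icp is not None:
        lines.append(f"# mr_icp_mmhg={float(record.mr_icp)!r}")
    four = record.arterial is not None and record.venous is not None
    if four:
        lines.append(",".join(_FOUR_COL))
        for i in range(cyc.frame_count):
            lines.append(
                f"{i},{float(record.arterial[i])!r},"
                f"{float(record.venous[i])!r},{float(cyc.q_csf[i])!r}"
            )
    else:
        lines.append(",".join(_THREE_COL))
        for i in range(cyc.frame_count):
            lines.append(f"{i},{float(cyc.q_av[i])!r},{float(cyc.q_csf[i])!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_waveforms(path: str | Path) -> SubjectRecord:
    """Parse a waveform CSV into a :class:`SubjectRecord`.

    Validates column dialect, numeric cells, contiguous frame indices and
    (when given) the frame_count metadata; runs the venous-onset QC rule when
    the four-column dialect supplies both blood waveforms.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if "=" in stripped:
                key, _, value = stripped.lstrip("#").partition("=")
                meta[key.strip()] = value.strip()
            continue
        body_lines.append(raw)
    if not body_lines:
        raise WaveformParseError(f"{path}: no data rows found")

    try:
        df = pd.read_csv(_io.StringIO("\n".join(body_lines)))
    except Exception as exc:  # malformed CSV structure
        raise WaveformParseError(f"{path}: {exc}") from exc

    cols = list(df.columns)
    if cols == _FOUR_COL:
        four = True
    elif cols == _THREE_COL:
        four = False
    else:
        raise WaveformParseError(
            f"{path}: unrecognised columns {cols}; expected {_THREE_COL} "
            f"or {_FOUR_COL}"
        )
    for col in cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise WaveformParseError(
                f"{path}: non-numeric or missing cell at row {row}, "
                f"column {col!r}"
            )
        df[col] = numeric

    frames = df["frame"].to_numpy()
    if not np.array_equal(frames, np.arange(len(frames))):
        raise WaveformParseError(
            f"{path}: frame column must run 0..{len(frames) - 1} contiguously"
        )
    if "frame_count" in meta:
        expected = int(meta["frame_count"])
        if len(df) != expected:
            raise WaveformParseError(
                f"{path}: {len(df)} rows but frame_count={expected} in metadata"
            )
    if "cycle_duration_s" not in meta:
        raise WaveformParseError(f"{path}: missing '# cycle_duration_s=' metadata")

    arterial = venous = None
    if four:
        arterial = df["arterial_ml_s"].to_numpy()
        venous = df["venous_ml_s"].to_numpy()
        q_av = net_transcranial_flow(arterial, venous)
    else:
        q_av = df["q_av_ml_s"].to_numpy()
    cycle = CardiacCycleData(
        q_av=q_av,
        q_csf=df["q_csf_ml_s"].to_numpy(),
        cycle_duration=float(meta["cycle_duration_s"]),
    )
    qc_flags: list[str] = []
    if four:
        flag = qc_venous_onset(arterial, venous)
        if flag is not None:
            qc_flags.append(flag)
    return SubjectRecord(
        subject_id=meta.get("subject_id", path.stem),
        cycle=cycle,
        age=int(meta["age"]) if "age" in meta else None,
        sex=meta.get("sex"),
        mr_icp=float(meta["mr_icp_mmhg"]) if "mr_icp_mmhg" in meta else None,
        qc_flags=qc_flags,
        arterial=arterial,
        venous=venous,
    )


def _age_band(age: int | None) -> str | None:
    if age is None:
        return None
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    return None


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p; (nan, nan) when undefined (constant input)."""
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cohort_summary(
    records: list[SubjectRecord],
    results: list,
) -> dict[str, pd.DataFrame]:
    """Stratified medians/IQRs and Pearson correlations for a cohort.

    ``results`` holds one DistributionResult per record (parallel lists).
    Returns a dict of DataFrames: ``by_age_band`` and ``by_sex`` give the
    median and interquartile range of the cranial contribution per stratum
    (empty strata are absent, not errors); ``correlations`` gives Pearson r
    and two-sided p for cranial percent vs age, cranial percent vs MR-ICP
    (when present) and spinal percent vs CSF stroke volume.  Correlations
    that are undefined (constant variable, or n < 2) are reported as NaN.
    """
    rows = []
    for rec, res in zip(records, results):
        caudal, _ = csf_stroke_volume(rec.cycle.q_csf, rec.cycle.cycle_duration)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "age": rec.age,
                "age_band": _age_band(rec.age),
                "sex": rec.sex,
                "mr_icp": rec.mr_icp,
                "cranial_percent": res.cranial_percent,
                "spinal_percent": res.spinal_percent,
                "stroke_volume_ml": caudal,
            }
        )
    df = pd.DataFrame(rows)

    def _strata(key: str) -> pd.DataFrame:
        sub = df.dropna(subset=[key])
        if sub.empty:
            return pd.DataFrame(
                columns=[key, "n", "median_cranial", "iqr_low", "iqr_high"]
            )
        out = []
        for name, grp in sub.groupby(key, sort=True):
            q1, med, q3 = np.percentile(grp["cranial_percent"], [25, 50, 75])
            out.append(
                {
                    key: name,
                    "n": len(grp),
                    "median_cranial": med,
                    "iqr_low": q1,
                    "iqr_high": q3,
                }
            )
        return pd.DataFrame(out)

    corr_rows = []
    pairs = [
        ("cranial_percent", "age"),
        ("cranial_percent", "mr_icp"),
        ("spinal_percent", "stroke_volume_ml"),
    ]
    for xcol, ycol in pairs:
        sub = df.dropna(subset=[xcol, ycol])
        r, p = _pearson(
            sub[xcol].to_numpy(dtype=float), sub[ycol].to_numpy(dtype=float)
        )
        corr_rows.append({"x": xcol, "y": ycol, "n": len(sub), "r": r, "p": p})

    return {
        "subjects": df,
        "by_age_band": _strata("age_band"),
        "by_sex": _strata("sex"),
        "correlations": pd.DataFrame(corr_rows),
    }
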