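"""fNIRS conditioning chain for tHb-based cerebrovascular reactivity.

Pipeline order (fixed, logged in the QC report):
tHb construction -> PCA systemic removal -> zero-phase band-pass ->
baseline subtraction / max normalization -> anti-correlation QC ->
ensemble averaging.

Inputs are oxy-/deoxy-hemoglobin concentration series (uM, 10 Hz); optical
density conversion and motion correction are out of scope (inputs are
assumed already in concentration units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ValidationError

#: default analysis band (Hz): neurovascular coupling frequencies
DEFAULT_BAND = (0.01, 0.05)


@dataclass
class SubjectRecord:
    """Per-subject, per-region oxy/deoxy channel series at a fixed rate."""

    subject_id: str
    region: str                       # "targeted" | "nontargeted"
    oxy: np.ndarray                   # (n_channels, n_samples), uM
    deoxy: np.ndarray                 # (n_channels, n_samples), uM
    sampling_rate: float = 10.0
    stim_onset: float = 120.0         # s
    baseline_window: float = 120.0    # s before onset
    qc: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.oxy = np.atleast_2d(np.asarray(self.oxy, float))
        self.deoxy = np.atleast_2d(np.asarray(self.deoxy, float))
        if self.oxy.shape != self.deoxy.shape:
            raise ValidationError("oxy/deoxy shapes differ")
        if self.baseline_window > self.stim_onset:
            raise ValidationError("baseline window must lie entirely pre-onset")

    @property
    def n_samples(self) -> int:
        return self.oxy.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


def compute_thb(record: SubjectRecord):
    """Total hemoglobin per channel and the regional mean series.

    tHb is the elementwise sum oxy + deoxy; the regional series is the mean
    over the region's channels.
    """
    if record.oxy.shape[1] != record.deoxy.shape[1]:
        raise ValidationError("oxy/deoxy length mismatch")
    thb = record.oxy + record.deoxy
    return thb, thb.mean(axis=0)


def bandpass(series: np.ndarray, rate: float, low: float = DEFAULT_BAND[0],
             high: float = DEFAULT_BAND[1], order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward).

    ``high`` may be the analysis-band edge 0.05 Hz or the broad-band
    0.1 Hz; the band must lie inside the Nyquist interval.
    """
    if not 0 < low < high:
        raise ValidationError("need 0 < low < high")
    if high >= rate / 2:
        raise ValidationError("band edge above Nyquist frequency")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    x = np.asarray(series, float)
    return sps.sosfiltfilt(sos, x, axis=-1)


def baseline_normalize(series: np.ndarray, rate: float, onset: float,
                       baseline_window: float):
    """Subtract the pre-onset baseline mean and scale by the post-onset peak.

    The normalization divides by the maximum absolute post-onset value so
    that the extremum maps to +1, or to -1 for initial-dip responses whose
    largest deviation is negative (reported through the flag).

    Returns
    -------
    (normalized, info) where info carries the scale factor, the extremum
    sign, and a ``degenerate`` flag when the series is constant (the
    normalization step is then skipped).
    """
    x = np.asarray(series, float)
    if baseline_window < 10.0:
        raise ValidationError("baseline window must be at least 10 s")
    i_on = int(round(onset * rate))
    i_b0 = int(round((onset - baseline_window) * rate))
    if i_b0 < 0 or i_on <= i_b0:
        raise ValidationError("baseline window outside the record")
    if np.all(x == 0):
        raise ValidationError("all-zero series cannot be normalized")
    base = x[i_b0:i_on].mean()
    y = x - base
    post = y[i_on:]
    peak = float(np.max(np.abs(post))) if post.size else 0.0
    if peak == 0.0:
        return y, {"scale": 1.0, "sign": 0, "degenerate": True}
    sign = int(np.sign(post[np.argmax(np.abs(post))]))
    return y / peak, {"scale": peak, "sign": sign, "degenerate": False}


def anticorrelation_qc(record: SubjectRecord, threshold: float = -0.5,
                       window: float = 600.0):
    """Oxy/deoxy anti-correlation signal-quality check.

    Pearson correlation between the regional oxy and deoxy means over the
    QC window; the record passes if r < threshold (default -0.5).
    """
    n_need = int(window * record.sampling_rate)
    if record.n_samples < n_need:
        raise ValidationError(f"QC window needs {window:.0f} s of data")
    oxy = record.oxy.mean(axis=0)[:n_need]
    deoxy = record.deoxy.mean(axis=0)[:n_need]
    if oxy.std() == 0 or deoxy.std() == 0:
        record.qc.update({"r": np.nan, "pass": False,
                          "reason": "constant series; correlation undefined"})
        return np.nan, False
    r = float(np.corrcoef(oxy, deoxy)[0, 1])
    ok = bool(r < threshold)
    record.qc.update({"r": r, "pass": ok})
    return r, ok


def pca_systemic_removal(channels: np.ndarray, n_components: int = 1,
                         fit_slice: slice | None = None) -> np.ndarray:
    """Remove the leading spatial covariance components across channels.

    ``channels`` is (n_channels, n_samples).  Channels are zero-meaned
    internally, the top ``n_components`` spatial principal components are
    projected out, and the channel means are restored.  This targets
    systemic physiology (e.g. a Mayer-wave common mode) shared across the
    spatially distributed montage.

    ``fit_slice`` restricts the samples used to *estimate* the spatial
    components (the projection is still applied to the whole record).  The
    study pipeline estimates them on the pre-stimulus baseline so the
    filter captures systemic physiology rather than the evoked response.
    """
    X = np.atleast_2d(np.asarray(channels, float))
    n_ch = X.shape[0]
    if n_ch < 2:
        raise ValidationError("PCA removal needs at least 2 channels")
    if n_components >= n_ch:
        raise ValidationError("n_components must be below the channel count")
    if n_components == 0:
        return X.copy()
    means = X.mean(axis=1, keepdims=True)
    Xc = X - means
    F = Xc if fit_slice is None else Xc[:, fit_slice]
    # spatial components: left singular vectors of the channel x time matrix
    U, s, Vt = np.linalg.svd(F - F.mean(axis=1, keepdims=True),
                             full_matrices=False)
    proj = U[:, :n_components]
    cleaned = Xc - proj @ (proj.T @ Xc)
    return cleaned + means


def ensemble_average(cohort):
    """Pointwise mean and standard deviation across aligned subject series."""
    series = [np.asarray(s, float) for s in cohort]
    if not series:
        raise ValidationError("empty cohort")
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise ValidationError("cohort series must share length")
    M = np.vstack(series)
    sd = M.std(axis=0, ddof=0) if len(series) > 1 else np.zeros(M.shape[1])
    return M.mean(axis=0), sd, len(series)


# ---------------------------------------------------------------------------
# Whole-chain convenience + tabular I/O
# ---------------------------------------------------------------------------

def preprocess_record(record: SubjectRecord, low: float = DEFAULT_BAND[0],
                      high: float = DEFAULT_BAND[1], n_components: int = 1,
                      qc_window: float = 600.0):
    """Run the fixed conditioning chain on one record.

    Returns a dict with the normalized regional tHb, QC outcome, and a log
    of the applied stages in order.
    """
    thb_ch, _ = compute_thb(record)
    base = slice(0, int(round(record.stim_onset * record.sampling_rate)))
    cleaned = (pca_systemic_removal(thb_ch, n_components, fit_slice=base)
               if n_components else thb_ch)
    filtered = bandpass(cleaned, record.sampling_rate, low, high)
    regional = filtered.mean(axis=0)
    normalized, norm_info = baseline_normalize(
        regional, record.sampling_rate, record.stim_onset, record.baseline_window)
    r, ok = anticorrelation_qc(record, window=qc_window)
    return {
        "subject": record.subject_id,
        "region": record.region,
        "times": record.times,
        "thb_normalized": normalized,
        "norm": norm_info,
        "qc_r": r,
        "qc_pass": ok,
        "stages": ["thb", f"pca_removal({n_components})",
                   f"bandpass({low}-{high} Hz)", "baseline_normalize", "qc"],
    }


def preprocess_subject(records, low: float = DEFAULT_BAND[0],
                       high: float = DEFAULT_BAND[1], n_components: int = 1,
                       qc_window: float = 600.0):
    """Run the conditioning chain on all of one subject's records jointly.

    The PCA systemic filter is estimated across the subject's *entire*
    montage (analysis regions plus any auxiliary ``"outer"`` channels) on
    the pre-stimulus baseline, then projected out of every channel; the
    remaining stages (band-pass, baseline/normalize, QC) run per analysis
    region.  Records with region ``"outer"`` contribute channels to the
    spatial filter but are not analyzed further.
    """
    if not records:
        raise ValidationError("no records given")
    rate = records[0].sampling_rate
    onset = records[0].stim_onset
    for r in records:
        if r.sampling_rate != rate or r.stim_onset != onset:
            raise ValidationError("subject records must share rate and onset")
    thb_blocks = [compute_thb(r)[0] for r in records]
    stacked = np.vstack(thb_blocks)
    base = slice(0, int(round(onset * rate)))
    cleaned = (pca_systemic_removal(stacked, n_components, fit_slice=base)
               if n_components else stacked)
    outs = []
    i = 0
    for rec, block in zip(records, thb_blocks):
        n_ch = block.shape[0]
        ch = cleaned[i:i + n_ch]
        i += n_ch
        if rec.region == "outer":
            continue
        filtered = bandpass(ch, rate, low, high)
        regional = filtered.mean(axis=0)
        normalized, norm_info = baseline_normalize(
            regional, rate, rec.stim_onset, rec.baseline_window)
        r, ok = anticorrelation_qc(rec, window=qc_window)
        outs.append({
            "subject": rec.subject_id, "region": rec.region,
            "times": rec.times, "thb_normalized": normalized,
            "norm": norm_info, "qc_r": r, "qc_pass": ok,
            "stim_onset": rec.stim_onset, "rate": rate,
            "stages": ["thb", f"pca_removal({n_components}, subject-level)",
                       f"bandpass({low}-{high} Hz)", "baseline_normalize",
                       "qc"],
        })
    return outs


def records_to_table(records) -> pd.DataFrame:
    """Long-format table (time, subject, region, channel, oxy, deoxy)."""
    rows = []
    for rec in records:
        t = rec.times
        for ch in range(rec.oxy.shape[0]):
            rows.append(pd.DataFrame({
                "time": t, "subject": rec.subject_id, "region": rec.region,
                "channel": ch, "oxy": rec.oxy[ch], "deoxy": rec.deoxy[ch]}))
    return pd.concat(rows, ignore_index=True)


def table_to_records(table, sampling_rate: float = 10.0,
                     stim_onset: float = 120.0,
                     baseline_window: float = 120.0):
    """Rebuild SubjectRecords from the long-format table."""
    df = pd.DataFrame(table)
    records = []
    for (subj, region), grp in df.groupby(["subject", "region"], sort=True):
        chans = sorted(grp["channel"].unique())
        oxy = np.vstack([grp[grp.channel == c].sort_values("time")["oxy"].to_numpy()
                         for c in chans])
        deoxy = np.vstack([grp[grp.channel == c].sort_values("time")["deoxy"].to_numpy()
                           for c in chans])
        records.append(SubjectRecord(str(subj), str(region), oxy, deoxy,
                                     sampling_rate, stim_onset, baseline_window))
    return records
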