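"""Denoising of extracted ROI BOLD time series.

The pipeline applies, in a fixed order:

1. outlier-frame detection — a frame is flagged when framewise
   displacement exceeds 0.9 mm or the global BOLD signal deviates from its
   mean by more than five standard deviations;
2. confound regression — ordinary least squares of each ROI series on an
   intercept plus the confound regressors (white-matter and CSF signals,
   motion parameters), keeping the residuals;
3. temporal band-pass filtering — zero-phase FFT-domain filter retaining
   0.008-0.09 Hz by default;
4. scrubbing — flagged frames are deleted before any correlation is
   computed; a subject with more than half of its frames flagged is
   marked unusable.

All thresholds and the band are configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

FD_THRESHOLD_MM = 0.9
GS_SD_THRESHOLD = 5.0
BAND_LOW_HZ = 0.008
BAND_HIGH_HZ = 0.09
MAX_FLAGGED_FRACTION = 0.5


@dataclass
class SubjectTimeSeries:
    """One subject's ROI x time matrix plus confounds and motion."""

    subject_id: str
    data: np.ndarray                     # (n_rois, n_timepoints)
    confounds: np.ndarray | None = None  # (n_confounds, n_timepoints)
    fd: np.ndarray | None = None         # mm per frame
    outlier_flags: np.ndarray | None = None
    usable: bool = True

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def global_signal(self) -> np.ndarray:
        return self.data.mean(axis=0)


@dataclass
class RoiTimeSeriesPanel:
    """A cohort of subject time series sharing ROI labels and TR."""

    subjects: list[SubjectTimeSeries]
    roi_labels: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        for s in self.subjects:
            if s.data.shape[0] != len(self.roi_labels):
                raise ValueError(
                    f"subject {s.subject_id}: {s.data.shape[0]} rows but "
                    f"{len(self.roi_labels)} ROI labels"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


def detect_outlier_frames(
    fd_series: np.ndarray,
    global_signal: np.ndarray,
    fd_threshold_mm: float = FD_THRESHOLD_MM,
    gs_sd_threshold: float = GS_SD_THRESHOLD,
) -> np.ndarray:
    """Flag frames with FD above threshold or a global-signal excursion."""
    fd = np.asarray(fd_series, dtype=float)
    gs = np.asarray(global_signal, dtype=float)
    if fd.size == 0 or gs.size == 0:
        raise ValueError("empty series")
    if fd.shape != gs.shape:
        raise ValueError("fd_series and global_signal must have equal length")
    sd = gs.std()
    gs_dev = np.abs(gs - gs.mean())
    gs_flag = gs_dev > gs_sd_threshold * sd if sd > 0 else np.zeros_like(gs, dtype=bool)
    return (fd > fd_threshold_mm) | gs_flag


def regress_confounds(subject: SubjectTimeSeries) -> SubjectTimeSeries:
    """Replace each ROI series with its OLS residual on [intercept | confounds].

    Rank-deficient confound matrices are handled by dropping dependent
    columns (with a warning); residuals are orthogonal to the retained
    regressors.
    """
    T = subject.n_timepoints
    if subject.confounds is None or subject.confounds.size == 0:
        design = np.ones((T, 1))
    else:
        C = np.asarray(subject.confounds, dtype=float).T  # (T, n_confounds)
        design = np.column_stack([np.ones(T), C])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # greedily keep a maximal independent column subset
            keep = [0]
            for j in range(1, design.shape[1]):
                cand = design[:, keep + [j]]
                if np.linalg.matrix_rank(cand) > len(keep):
                    keep.append(j)
            warnings.warn(
                f"subject {subject.subject_id}: dropped "
                f"{design.shape[1] - len(keep)} linearly dependent confound column(s)",
                stacklevel=2,
            )
            design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, subject.data.T, rcond=None)
    residuals = subject.data.T - design @ beta
    return replace(subject, data=residuals.T)


def bandpass_filter(
    subject: SubjectTimeSeries,
    tr_seconds: float,
    low_hz: float = BAND_LOW_HZ,
    high_hz: float = BAND_HIGH_HZ,
) -> SubjectTimeSeries:
    """Zero-phase FFT band-pass: keep frequency bins in [low_hz, high_hz]."""
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist:
        raise ValueError(
            f"high cut {high_hz} Hz exceeds the Nyquist frequency "
            f"{nyquist:.4f} Hz for TR = {tr_seconds} s"
        )
    T = subject.n_timepoints
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum = np.fft.rfft(subject.data, axis=1)
    spectrum[:, ~keep] = 0.0
    filtered = np.fft.irfft(spectrum, n=T, axis=1)
    return replace(subject, data=filtered)


def scrub(subject: SubjectTimeSeries) -> SubjectTimeSeries:
    """Delete flagged frames; mark the subject unusable when > 50% are flagged."""
    if subject.outlier_flags is None:
        raise ValueError("outlier_flags not set; run detect_outlier_frames first")
    flags = np.asarray(subject.outlier_flags, dtype=bool)
    frac = flags.mean()
    if frac > MAX_FLAGGED_FRACTION:
        logger.warning(
            "subject %s: %.0f%% of frames flagged; marked unusable",
            subject.subject_id, 100 * frac,
        )
        return replace(subject, usable=False)
    keep = ~flags
    new = replace(
        subject,
        data=subject.data[:, keep],
        confounds=None if subject.confounds is None else subject.confounds[:, keep],
        fd=None if subject.fd is None else subject.fd[keep],
        outlier_flags=np.zeros(int(keep.sum()), dtype=bool),
    )
    logger.info(
        "subject %s: scrubbed %d of %d frames", subject.subject_id,
        int(flags.sum()), flags.size,
    )
    return new


def preprocess_subject(
    subject: SubjectTimeSeries,
    tr_seconds: float,
    fd_threshold_mm: float = FD_THRESHOLD_MM,
    gs_sd_threshold: float = GS_SD_THRESHOLD,
    low_hz: float = BAND_LOW_HZ,
    high_hz: float = BAND_HIGH_HZ,
) -> SubjectTimeSeries:
    """Fixed-order denoising: detect -> regress -> band-pass -> scrub."""
    fd = subject.fd if subject.fd is not None else np.zeros(subject.n_timepoints)
    flags = detect_outlier_frames(
        fd, subject.global_signal(), fd_threshold_mm, gs_sd_threshold
    )
    subject = replace(subject, outlier_flags=flags)
    subject = regress_confounds(subject)
    subject = bandpass_filter(subject, tr_seconds, low_hz, high_hz)
    return scrub(subject)


def preprocess_panel(panel: RoiTimeSeriesPanel, **kwargs) -> RoiTimeSeriesPanel:
    """Denoise every subject; unusable subjects are retained but flagged."""
    done = [preprocess_subject(s, panel.tr_seconds, **kwargs) for s in panel.subjects]
    return RoiTimeSeriesPanel(done, panel.roi_labels, panel.tr_seconds)
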