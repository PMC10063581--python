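"""Per-stimulus acoustic descriptors for timbre modeling.

Spectral descriptors (centroid, bandwidth, crest, flatness, 85% rolloff)
are computed per STFT frame and summarized as median and interquartile
range over frames that pass a silence gate (frames more than 60 dB below
the loudest frame are ignored).  Pitch (F0) and the harmonic-to-noise
ratio come from the normalized autocorrelation of long analysis frames:
the height r of the strongest autocorrelation peak in the lag range of
plausible periods gives F0 = fs / lag and HNR = 10*log10(r / (1 - r)).
Attack descriptors (attack slope, log attack time, temporal centroid) are
read off a smoothed RMS energy envelope.  MPS roughness is the mean power
of the modulation power spectrum — the 2-D Fourier transform of the
mean-removed log-magnitude spectrogram — inside the 30-150 Hz temporal-
modulation band (both signs), averaged over all spectral-modulation rows;
it responds to fast amplitude fluctuation, the classical acoustic
correlate of auditory roughness.

Meta features (instrument family, playing technique) are one-hot encoded,
and highly collinear acoustic columns can be pruned greedily by pairwise
Pearson correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .corpus import SoundStimulus

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameConfig:
    """STFT and envelope analysis parameters (seconds)."""

    window_s: float = 0.025
    hop_s: float = 0.010
    silence_gate_db: float = 60.0
    # MPS needs hop <= 1/300 s so the temporal-modulation Nyquist clears the
    # 30-150 Hz band, and a window short enough (~10 ms) that its spectral
    # mainlobe does not smear envelope ripple inside that band
    mps_window_s: float = 0.010
    mps_hop_s: float = 0.0025
    f0_min_hz: float = 25.0
    f0_max_hz: float = 4500.0
    f0_window_s: float = 0.1
    f0_hop_s: float = 0.025
    voicing_threshold: float = 0.5


ACOUSTIC_FEATURES = [
    "spectral_centroid_med", "spectral_centroid_iqr",
    "spectral_bandwidth_med", "spectral_bandwidth_iqr",
    "spectral_crest_med", "spectral_crest_iqr",
    "spectral_flatness_med", "spectral_flatness_iqr",
    "spectral_rolloff_med", "spectral_rolloff_iqr",
    "f0_med", "hnr",
    "attack_slope", "log_attack_time", "temporal_centroid",
    "mps_roughness",
]


@dataclass
class FrameSpectra:
    stimulus_id: str
    frame_times: np.ndarray
    frequencies: np.ndarray
    magnitudes: np.ndarray  # frames x bins, >= 0
    window_s: float
    hop_s: float


@dataclass
class FeatureMatrix:
    """Feature table (rows = stimuli) with column metadata and a pruning log."""

    data: pd.DataFrame
    column_meta: pd.DataFrame  # name, unit, kind in {acoustic, meta}
    pruning_log: list[dict] = field(default_factory=list)

    @property
    def acoustic_columns(self) -> list[str]:
        return list(self.column_meta.loc[self.column_meta["kind"] == "acoustic", "name"])

    @property
    def meta_columns(self) -> list[str]:
        return list(self.column_meta.loc[self.column_meta["kind"] == "meta", "name"])

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path)
        sidecar = Path(path).with_suffix(".columns.json")
        sidecar.write_text(
            json.dumps(
                {
                    "columns": self.column_meta.to_dict(orient="records"),
                    "pruning_log": self.pruning_log,
                },
                indent=1,
            )
        )


# ---------------------------------------------------------------------------
# STFT and spectral descriptors
# ---------------------------------------------------------------------------


def frame_spectra(stim: SoundStimulus, cfg: FrameConfig = FrameConfig()) -> FrameSpectra:
    fs = stim.sample_rate_hz
    nperseg = max(int(round(cfg.window_s * fs)), 16)
    hop = max(int(round(cfg.hop_s * fs)), 1)
    if len(stim.samples) < 2 * nperseg:
        raise ValueError("signal shorter than two analysis frames")
    f, t, z = sps.stft(
        stim.samples, fs=fs, nperseg=nperseg, noverlap=nperseg - hop,
        boundary=None, padded=False,
    )
    return FrameSpectra(stim.stimulus_id, t, f, np.abs(z).T, cfg.window_s, cfg.hop_s)


def _gated_frames(mags: np.ndarray, gate_db: float) -> np.ndarray:
    power = np.sum(mags**2, axis=1)
    peak = power.max()
    if peak <= 0:
        raise ValueError("all-silent input")
    return power > peak * 10.0 ** (-gate_db / 10.0)


def spectral_descriptors(
    stim: SoundStimulus, cfg: FrameConfig = FrameConfig()
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-frame spectral descriptor series plus median/IQR summaries."""
    spec = frame_spectra(stim, cfg)
    mags = spec.magnitudes
    freqs = spec.frequencies
    keep = _gated_frames(mags, cfg.silence_gate_db)
    mags = mags[keep]
    eps = 1e-12
    total = mags.sum(axis=1) + eps
    centroid = (mags * freqs).sum(axis=1) / total
    bandwidth = np.sqrt((mags * (freqs - centroid[:, None]) ** 2).sum(axis=1) / total)
    crest = mags.max(axis=1) / (mags.mean(axis=1) + eps)
    flatness = np.exp(np.mean(np.log(mags + eps), axis=1)) / (mags.mean(axis=1) + eps)
    energy = mags**2
    cum = np.cumsum(energy, axis=1)
    thresh = 0.85 * cum[:, -1]
    rolloff = freqs[np.argmax(cum >= thresh[:, None], axis=1)]
    series = pd.DataFrame(
        {
            "time_s": spec.frame_times[keep],
            "spectral_centroid": centroid,
            "spectral_bandwidth": bandwidth,
            "spectral_crest": crest,
            "spectral_flatness": flatness,
            "spectral_rolloff": rolloff,
        }
    )
    summaries: dict[str, float] = {}
    for name in ("spectral_centroid", "spectral_bandwidth", "spectral_crest",
                 "spectral_flatness", "spectral_rolloff"):
        vals = series[name].to_numpy()
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        summaries[f"{name}_med"] = float(med)
        summaries[f"{name}_iqr"] = float(q75 - q25)
    return series, summaries


# ---------------------------------------------------------------------------
# F0 and HNR from frame autocorrelation
# ---------------------------------------------------------------------------


def _frame_autocorr_peaks(
    stim: SoundStimulus, cfg: FrameConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(peak harmonicity r, F0 estimate) per gated analysis frame."""
    fs = stim.sample_rate_hz
    x = np.asarray(stim.samples, float)
    win = int(cfg.f0_window_s * fs)
    hop = int(cfg.f0_hop_s * fs)
    if len(x) < win:
        win = len(x)
    lag_min = max(int(fs / cfg.f0_max_hz), 2)
    lag_max = min(int(fs / cfg.f0_min_hz), win - 2)
    if lag_max <= lag_min:
        raise ValueError("analysis window too short for the F0 search range")
    starts = range(0, max(len(x) - win, 0) + 1, hop)
    frames = np.stack([x[s : s + win] for s in starts])
    frames = frames - frames.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    if rms.max() <= 0:
        raise ValueError("all-silent input")
    frames = frames[rms > rms.max() * 10 ** (-cfg.silence_gate_db / 20.0)]
    if len(frames) == 0:
        raise ValueError("all-silent input")
    nfft = int(2 ** np.ceil(np.log2(2 * win)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, axis=1)[:, : lag_max + 1]
    ac0 = ac[:, 0].copy()
    ac0[ac0 <= 0] = 1.0
    # unbiased normalization: the biased FFT estimate sums only win - tau
    # products, which would deflate the peak at the period lag
    unbias = win / np.maximum(win - np.arange(lag_max + 1), 1)
    acn = np.clip(ac / ac0[:, None] * unbias[None, :], -1.0, 1.0)
    # candidate periods are local autocorrelation maxima; a small per-octave
    # lag penalty steers the pick away from subharmonic lags (integer
    # multiples of the period score the same r)
    lag_grid = np.arange(lag_min, lag_max + 1)
    lag_penalty = 0.01 * np.log2(lag_grid / lag_min)
    r = np.zeros(len(acn))
    f0 = np.full(len(acn), np.nan)
    for i, row in enumerate(acn):
        seg = row[lag_min : lag_max + 1]
        peaks, _ = sps.find_peaks(seg)
        if len(peaks) == 0:
            continue
        best = peaks[np.argmax(seg[peaks] - lag_penalty[peaks])]
        lag = best + lag_min
        # parabolic interpolation of lag and peak height
        y0, y1, y2 = row[lag - 1], row[lag], row[lag + 1]
        denom = y0 - 2 * y1 + y2
        shift = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)) if denom != 0 else 0.0
        r[i] = min(float(y1 - 0.25 * (y0 - y2) * shift), 1.0)
        f0[i] = fs / (lag + shift)
    return r, f0


def estimate_f0(
    stim: SoundStimulus,
    fmin: float | None = None,
    fmax: float | None = None,
    cfg: FrameConfig = FrameConfig(),
) -> float:
    """Median F0 (Hz) over voiced frames; NaN if no frame is periodic."""
    if fmin is not None or fmax is not None:
        cfg = FrameConfig(
            **{
                **cfg.__dict__,
                "f0_min_hz": fmin if fmin is not None else cfg.f0_min_hz,
                "f0_max_hz": fmax if fmax is not None else cfg.f0_max_hz,
            }
        )
    r, f0 = _frame_autocorr_peaks(stim, cfg)
    voiced = r >= cfg.voicing_threshold
    if not np.any(voiced):
        return float("nan")
    return float(np.median(f0[voiced]))


def hnr(stim: SoundStimulus, cfg: FrameConfig = FrameConfig()) -> float:
    """Harmonic-to-noise ratio in dB: median of 10*log10(r / (1-r))."""
    r, _ = _frame_autocorr_peaks(stim, cfg)
    r = np.clip(r, 1e-6, 1.0 - 1e-6)
    return float(np.median(10.0 * np.log10(r / (1.0 - r))))


# ---------------------------------------------------------------------------
# Attack / temporal descriptors
# ---------------------------------------------------------------------------


def energy_envelope(stim: SoundStimulus, frame_s: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    fs = stim.sample_rate_hz
    n = max(int(frame_s * fs), 1)
    x = np.asarray(stim.samples, float)
    n_frames = len(x) // n
    if n_frames < 3:
        raise ValueError("signal too short for an energy envelope")
    env = np.sqrt(np.mean(x[: n_frames * n].reshape(n_frames, n) ** 2, axis=1))
    env = np.convolve(env, np.ones(3) / 3.0, mode="same")  # light smoothing
    times = (np.arange(n_frames) + 0.5) * n / fs
    return times, env


def attack_features(stim: SoundStimulus) -> dict[str, float]:
    """Attack slope (1/s), log10 attack time, and temporal centroid (s).

    The attack is the 10%-to-90% rise of the smoothed RMS envelope before
    its peak; slope = 0.8 * max / (t90 - t10) on the max-normalized
    envelope.  A flat envelope yields NaN slope (flagged downstream).
    """
    times, env = energy_envelope(stim)
    peak = env.max()
    if peak <= 0:
        raise ValueError("all-silent input")
    envn = env / peak
    ipk = int(np.argmax(envn))
    pre = envn[: ipk + 1]
    i10 = int(np.argmax(pre >= 0.1))
    i90 = int(np.argmax(pre >= 0.9))
    t10, t90 = times[i10], times[i90]
    rise = t90 - t10
    min_rise = times[1] - times[0] if len(times) > 1 else 0.001
    rise = max(rise, min_rise)  # quantization floor: one envelope frame
    slope = 0.8 / rise
    tc = float(np.sum(times * env**2) / np.sum(env**2))
    return {
        "attack_slope": float(slope),
        "log_attack_time": float(np.log10(rise)),
        "temporal_centroid": tc,
    }


# ---------------------------------------------------------------------------
# Modulation power spectrum roughness
# ---------------------------------------------------------------------------


def mps_roughness(
    stim: SoundStimulus,
    band: tuple[float, float] = (30.0, 150.0),
    cfg: FrameConfig = FrameConfig(),
) -> float:
    """Mean modulation power in the 30-150 Hz temporal-modulation band.

    Computed from the 2-D FFT of the mean-removed log-magnitude
    spectrogram; both positive and negative temporal-modulation
    frequencies are included and all spectral-modulation rows averaged.
    Digital silence returns exactly 0.
    """
    fs = stim.sample_rate_hz
    nperseg = max(int(round(cfg.mps_window_s * fs)), 16)
    hop = max(int(round(cfg.mps_hop_s * fs)), 1)
    if len(stim.samples) < 2 * nperseg:
        raise ValueError("signal too short for the modulation power spectrum")
    mod_nyquist = 1.0 / (2.0 * cfg.mps_hop_s)
    if mod_nyquist < band[1]:
        raise ValueError(
            f"mps_hop_s={cfg.mps_hop_s} gives temporal-modulation Nyquist "
            f"{mod_nyquist:.0f} Hz < band top {band[1]:.0f} Hz"
        )
    _, t, z = sps.stft(
        stim.samples, fs=fs, nperseg=nperseg, noverlap=nperseg - hop,
        boundary=None, padded=False,
    )
    mag = np.abs(z)
    if mag.max() <= 0:
        return 0.0
    logmag = 20.0 * np.log10(mag + 1e-10)
    # floor 80 dB below the peak so empty bins do not dominate the transform
    logmag = np.maximum(logmag, logmag.max() - 80.0)
    logmag = logmag - logmag.mean()
    mps = np.abs(np.fft.fft2(logmag)) ** 2 / logmag.size
    tmod = np.fft.fftfreq(logmag.shape[1], d=hop / fs)
    in_band = (np.abs(tmod) >= band[0]) & (np.abs(tmod) <= band[1])
    if not np.any(in_band):
        raise ValueError("no modulation bins inside the band")
    return float(mps[:, in_band].mean())


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------


def extract_features(stim: SoundStimulus, cfg: FrameConfig = FrameConfig()) -> dict[str, float]:
    """One complete acoustic feature vector for a stimulus."""
    _, out = spectral_descriptors(stim, cfg)
    r, f0_all = _frame_autocorr_peaks(stim, cfg)
    voiced = r >= cfg.voicing_threshold
    out["f0_med"] = float(np.median(f0_all[voiced])) if np.any(voiced) else float("nan")
    rr = np.clip(r, 1e-6, 1.0 - 1e-6)
    out["hnr"] = float(np.median(10.0 * np.log10(rr / (1.0 - rr))))
    out.update(attack_features(stim))
    out["mps_roughness"] = mps_roughness(stim, cfg=cfg)
    return out


def one_hot_meta(meta: pd.DataFrame, categories: Sequence[str] = ("family", "technique")) -> pd.DataFrame:
    """Indicator columns per category level; exactly one 1 per row per category."""
    missing = [c for c in categories if c not in meta.columns]
    if missing:
        raise ValueError(f"missing categorical columns: {missing}")
    for c in categories:
        if meta[c].isna().any():
            raise ValueError(f"unknown (missing) label in column {c!r}")
    out = pd.get_dummies(meta[list(categories)], prefix=categories, dtype=int)
    out.index = meta.index
    return out


def decode_one_hot(onehot: pd.DataFrame, category: str) -> pd.Series:
    cols = [c for c in onehot.columns if c.startswith(f"{category}_")]
    labels = onehot[cols].idxmax(axis=1).str[len(category) + 1 :]
    return labels.rename(category)


def build_feature_matrix(
    stimuli: Sequence[SoundStimulus],
    meta: pd.DataFrame | None = None,
    cfg: FrameConfig = FrameConfig(),
    f0_fallback_hz: float | None = None,
) -> FeatureMatrix:
    """Extract all stimuli into a FeatureMatrix (plus optional one-hot meta).

    Unvoiced stimuli get ``f0_fallback_hz`` (default: the F0 search floor)
    and the substitution is recorded in the pruning/extraction log.
    """
    log: list[dict] = []
    fallback = cfg.f0_min_hz if f0_fallback_hz is None else f0_fallback_hz
    rows = {}
    for s in stimuli:
        feats = extract_features(s, cfg)
        if np.isnan(feats["f0_med"]):
            feats["f0_med"] = fallback
            log.append({"stimulus_id": s.stimulus_id, "action": "f0_unvoiced_fallback",
                        "value": fallback})
        rows[s.stimulus_id] = feats
    data = pd.DataFrame.from_dict(rows, orient="index").loc[:, ACOUSTIC_FEATURES]
    data.index.name = "stimulus_id"
    meta_cols: list[str] = []
    if meta is not None:
        onehot = one_hot_meta(meta.set_index("stimulus_id").loc[data.index])
        data = pd.concat([data, onehot], axis=1)
        meta_cols = list(onehot.columns)
    units = {
        "spectral_centroid_med": "Hz", "spectral_centroid_iqr": "Hz",
        "spectral_bandwidth_med": "Hz", "spectral_bandwidth_iqr": "Hz",
        "spectral_rolloff_med": "Hz", "spectral_rolloff_iqr": "Hz",
        "f0_med": "Hz", "hnr": "dB", "attack_slope": "1/s",
        "log_attack_time": "log10 s", "temporal_centroid": "s",
        "mps_roughness": "power",
    }
    column_meta = pd.DataFrame(
        [{"name": c, "unit": units.get(c, ""), "kind": "acoustic"} for c in ACOUSTIC_FEATURES]
        + [{"name": c, "unit": "", "kind": "meta"} for c in meta_cols]
    )
    return FeatureMatrix(data=data, column_meta=column_meta, pruning_log=log)


def prune_multicollinear(matrix: FeatureMatrix, r_threshold: float = 0.9) -> FeatureMatrix:
    """Greedily drop acoustic columns until no pair has |Pearson r| > threshold.

    Of the offending pair, the member with the larger mean absolute
    correlation to all other acoustic columns is removed; meta columns are
    exempt.  Every removal is appended to the pruning log.
    """
    data = matrix.data.copy()
    acoustic = [c for c in matrix.acoustic_columns if c in data.columns]
    log = list(matrix.pruning_log)
    while len(acoustic) >= 2:
        corr = data[acoustic].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        # constant columns give NaN correlations; treat as uncorrelated
        corr = corr.fillna(0.0)
        max_r = corr.values.max()
        if max_r <= r_threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        drop = a if corr.loc[a].mean() >= corr.loc[b].mean() else b
        keep = b if drop == a else a
        log.append({"action": "pruned", "column": drop, "r": float(max_r), "against": keep})
        data = data.drop(columns=[drop])
        acoustic.remove(drop)
    column_meta = matrix.column_meta[matrix.column_meta["name"].isin(data.columns)].reset_index(drop=True)
    return FeatureMatrix(data=data, column_meta=column_meta, pruning_log=log)
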