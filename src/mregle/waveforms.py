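"""Waveform preprocessing: filtering, QC, scaling, splitting and fusion.

The pipeline consumes per-individual fixed-length median waveforms (an ECG
median complex of 600 samples per lead, a PPG median beat of 100 samples,
optionally a spirogram curve), cleans them, rescales each modality so its
values fall roughly in [-1, 1], assigns deterministic train/val/test splits,
and fuses the modalities into a single model-ready tensor — either by
stacking equal-length leads as channels or by concatenating the waveforms
into one long single-channel record.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "DEFAULT_REGISTRY",
    "ECG_LEADS",
    "WaveformRecord",
    "MultimodalSample",
    "FusionSpec",
    "FusedTensor",
    "fir_bandpass",
    "qc_filter",
    "compute_scale_factor",
    "assign_split",
    "fuse",
    "unfuse",
    "read_waveform_table",
    "write_waveform_table",
    "write_split_manifest",
    "read_split_manifest",
]

ECG_LEADS = (
    "ECG_leadI", "ECG_leadII", "ECG_leadIII", "ECG_aVR", "ECG_aVL", "ECG_aVF",
    "ECG_V1", "ECG_V2", "ECG_V3", "ECG_V4", "ECG_V5", "ECG_V6",
)

#: Registered per-modality waveform lengths. ECG median complexes carry 600
#: samples per lead; the PPG median beat carries 100; the spirogram default
#: (300) is the synthetic generator's choice and is overridable.
DEFAULT_REGISTRY: dict[str, int] = {**{lead: 600 for lead in ECG_LEADS}, "PPG": 100, "SPIRO": 300}

Split = Literal["train", "val", "test"]


@dataclass
class WaveformRecord:
    """One fixed-length waveform for one individual and one modality."""

    sample_id: str
    modality: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("waveform values must be a nonempty 1-D sequence")

    @property
    def length(self) -> int:
        return int(self.values.size)

    def validate(self, registry: Mapping[str, int] = DEFAULT_REGISTRY) -> None:
        expected = registry.get(self.modality)
        if expected is not None and self.length != expected:
            raise ValueError(
                f"{self.modality} waveform for {self.sample_id!r} has length "
                f"{self.length}, registry expects {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in waveform {self.sample_id!r}/{self.modality}")


@dataclass
class MultimodalSample:
    """All registered modalities plus covariates for one individual."""

    sample_id: str
    waveforms: dict[str, WaveformRecord]
    covariates: dict[str, float] = field(default_factory=dict)
    split: Split | None = None

    def require(self, modalities: Iterable[str]) -> None:
        missing = [m for m in modalities if m not in self.waveforms]
        if missing:
            raise KeyError(f"sample {self.sample_id!r} is missing modalities {missing}")


@dataclass
class FusionSpec:
    """How to combine modalities into one model input.

    ``channel_stack`` requires equal lengths and produces an (n, L, C) array
    (the 12-lead ECG case: 600 x 12); ``concatenate`` joins the scaled
    waveforms end-to-end into one channel (lead I ECG + PPG: 700 points).
    """

    strategy: Literal["channel_stack", "concatenate"]
    modality_order: tuple[str, ...]
    scale_factors: dict[str, float]

    def __post_init__(self) -> None:
        self.modality_order = tuple(self.modality_order)
        if len(set(self.modality_order)) != len(self.modality_order):
            raise ValueError("modality_order must list every modality exactly once")
        if self.strategy not in ("channel_stack", "concatenate"):
            raise ValueError(f"unknown fusion strategy {self.strategy!r}")
        for m in self.modality_order:
            f = self.scale_factors.get(m)
            if f is None or not np.isfinite(f) or f <= 0:
                raise ValueError(f"scale factor for {m!r} must be a positive real, got {f}")


@dataclass
class FusedTensor:
    """Model-ready fused array plus the spec that produced it."""

    sample_ids: list[str]
    data: np.ndarray  # (n, L, C) for channel_stack, (n, T) for concatenate
    spec: FusionSpec
    lengths: dict[str, int]

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """2-D (n, features) view used by the representation models."""
        return self.data.reshape(self.data.shape[0], -1)

    def modality_slices(self) -> dict[str, tuple]:
        """Index (into ``data``'s trailing axes) of each modality's block."""
        out: dict[str, tuple] = {}
        if self.spec.strategy == "channel_stack":
            for c, m in enumerate(self.spec.modality_order):
                out[m] = (slice(None), slice(None), c)
        else:
            start = 0
            for m in self.spec.modality_order:
                stop = start + self.lengths[m]
                out[m] = (slice(None), slice(start, stop))
                start = stop
        return out


# ---------------------------------------------------------------------------
# filtering


def design_fir_bandpass(low_hz: float, high_hz: float, sampling_hz: float = 500.0,
                        taps: int = 255) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass kernel with exactly zero DC gain.

    The default corners (0.05 Hz, 40 Hz) remove baseline wander and
    high-frequency noise. At 255 taps and 500 Hz the 0.05 Hz corner sits far
    below the kernel's frequency resolution, so the designed kernel is
    re-centered to sum to zero: constant offsets are then rejected exactly
    while the pass band is perturbed only by the (tiny) removed DC residue.
    """
    if taps % 2 == 0:
        raise ValueError("taps must be odd for a symmetric zero-phase design")
    if not (0.0 < low_hz < high_hz < sampling_hz / 2.0):
        raise ValueError(
            f"cutoffs must satisfy 0 < low < high < Nyquist; got "
            f"low={low_hz}, high={high_hz}, fs={sampling_hz}"
        )
    h = signal.firwin(taps, [low_hz, high_hz], pass_zero=False, fs=sampling_hz,
                      window="hamming")
    return h - h.sum() / taps


def fir_bandpass(record: WaveformRecord, low_hz: float = 0.05, high_hz: float = 40.0,
                 sampling_hz: float = 500.0, taps: int = 255) -> WaveformRecord:
    """Zero-phase band-pass filter of a single waveform.

    Applied forward-backward (``filtfilt``) so the output is same-length and
    phase-compensated; the effective amplitude response is the square of the
    designed kernel's.
    """
    h = design_fir_bandpass(low_hz, high_hz, sampling_hz, taps)
    padlen = min(3 * taps, record.length - 1)
    filtered = signal.filtfilt(h, [1.0], record.values, padlen=padlen)
    return WaveformRecord(record.sample_id, record.modality, filtered)


def filter_samples(samples: Sequence[MultimodalSample], modalities: Iterable[str] | None = None,
                   low_hz: float = 0.05, high_hz: float = 40.0, sampling_hz: float = 500.0,
                   taps: int = 255) -> list[MultimodalSample]:
    """Band-pass filter selected modalities of every sample.

    By default only ECG leads are filtered; the PPG median beat is already
    clean and is passed through untouched.
    """
    out = []
    for s in samples:
        if modalities is None:
            targets = [m for m in s.waveforms if m.startswith("ECG")]
        else:
            targets = list(modalities)
        wf = dict(s.waveforms)
        for m in targets:
            if m in wf:
                wf[m] = fir_bandpass(wf[m], low_hz, high_hz, sampling_hz, taps)
        out.append(MultimodalSample(s.sample_id, wf, dict(s.covariates), s.split))
    return out


# ---------------------------------------------------------------------------
# quality control


def _record_stats(values: np.ndarray) -> np.ndarray:
    return np.array([values.min(), values.max(), values.mean(), np.median(values)])


def qc_filter(records: Sequence[WaveformRecord], pct_low: float = 0.1,
              pct_high: float = 99.9) -> tuple[list[str], dict[str, str]]:
    """Percentile-based outlier removal within one modality.

    Four summary statistics (minimum, maximum, mean, median) are computed per
    waveform; a record is dropped iff at least one statistic falls strictly
    outside the inclusive [pct_low, pct_high] percentile interval of that
    statistic across all records of the modality.  The cutoffs are the
    outer order statistics bracketing the requested percentiles (the low
    bound rounds down, the high bound rounds up), so the bounds are always
    attainable by the data: constant datasets and two-record inputs survive
    intact.

    Returns (kept sample_ids, dropped sample_id -> reason).
    """
    if len(records) < 2:
        raise ValueError("qc_filter needs at least two records per modality")
    modalities = {r.modality for r in records}
    if len(modalities) != 1:
        raise ValueError(f"qc_filter operates on one modality at a time, got {modalities}")

    finite = [r for r in records if np.all(np.isfinite(r.values))]
    dropped: dict[str, str] = {
        r.sample_id: "non-finite" for r in records if not np.all(np.isfinite(r.values))
    }
    if not finite:
        raise ValueError("no finite records left after removing non-finite waveforms")

    stats = np.stack([_record_stats(r.values) for r in finite])  # (n, 4)
    lo = np.percentile(stats, pct_low, axis=0, method="lower")
    hi = np.percentile(stats, pct_high, axis=0, method="higher")
    stat_names = ("min", "max", "mean", "median")

    kept: list[str] = []
    for r, row in zip(finite, stats):
        bad = [nm for nm, v, a, b in zip(stat_names, row, lo, hi) if v < a or v > b]
        if bad:
            dropped[r.sample_id] = f"outlier:{','.join(bad)}"
        else:
            kept.append(r.sample_id)
    return kept, dropped


def qc_filter_samples(samples: Sequence[MultimodalSample], modalities: Iterable[str],
                      pct_low: float = 0.1, pct_high: float = 99.9,
                      ) -> tuple[list[MultimodalSample], dict[str, str]]:
    """Apply :func:`qc_filter` per modality and keep complete passing samples."""
    modalities = list(modalities)
    dropped_all: dict[str, str] = {}
    kept_ids = {s.sample_id for s in samples}
    for m in modalities:
        recs = [s.waveforms[m] for s in samples if m in s.waveforms]
        kept, dropped = qc_filter(recs, pct_low, pct_high)
        kept_ids &= set(kept)
        for sid, reason in dropped.items():
            dropped_all.setdefault(sid, f"{m}:{reason}")
    return [s for s in samples if s.sample_id in kept_ids], dropped_all


# ---------------------------------------------------------------------------
# scaling and splits


def compute_scale_factor(training_records: Sequence[WaveformRecord]) -> float:
    """90th percentile of per-waveform max |value| over the *training* split.

    Dividing every waveform of the modality (all splits) by this factor puts
    at least ~90% of training waveforms inside [-1, 1] while ignoring extreme
    outliers.  Linear-interpolation percentile estimator throughout.
    """
    if len(training_records) == 0:
        raise ValueError("cannot compute a scale factor from an empty training set")
    abs_max = np.array([np.abs(r.values).max() for r in training_records])
    factor = float(np.percentile(abs_max, 90.0, method="linear"))
    if factor <= 0.0:
        raise ValueError("scale factor is zero (all-zero training waveforms)")
    return factor


def compute_scale_factors(samples: Sequence[MultimodalSample], modalities: Iterable[str],
                          ) -> dict[str, float]:
    """Per-modality scale factors from the samples assigned to the train split."""
    train = [s for s in samples if s.split == "train"]
    if not train:
        raise ValueError("no training-split samples to compute scale factors from")
    return {m: compute_scale_factor([s.waveforms[m] for s in train]) for m in modalities}


_SPLIT_BUCKETS = 1000


def assign_split(sample_id: str, fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
                 ) -> Split:
    """Deterministic, platform-independent split from a static hash of the id.

    The first 8 bytes of the SHA-256 digest of the id string, taken modulo
    1000, index one of 1000 buckets; buckets are allotted to train/val/test
    in proportion to ``fractions`` (0-699 / 700-899 / 900-999 at the default
    70/20/10).  The same id always maps to the same split, on any machine.
    """
    if not sample_id:
        raise ValueError("sample_id must be nonempty")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    digest = hashlib.sha256(sample_id.encode("utf-8")).digest()
    bucket = int.from_bytes(digest[:8], "big") % _SPLIT_BUCKETS
    train_hi = round(fractions[0] * _SPLIT_BUCKETS)
    val_hi = train_hi + round(fractions[1] * _SPLIT_BUCKETS)
    if bucket < train_hi:
        return "train"
    if bucket < val_hi:
        return "val"
    return "test"


def assign_splits(samples: Sequence[MultimodalSample],
                  fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
                  ) -> list[MultimodalSample]:
    for s in samples:
        s.split = assign_split(s.sample_id, fractions)
    return list(samples)


# ---------------------------------------------------------------------------
# fusion


def fuse(samples: Sequence[MultimodalSample], spec: FusionSpec,
         registry: Mapping[str, int] = DEFAULT_REGISTRY) -> FusedTensor:
    """Scale each modality by its factor and fuse per ``spec``."""
    if not samples:
        raise ValueError("no samples to fuse")
    lengths: dict[str, int] = {}
    for m in spec.modality_order:
        ln = registry.get(m)
        if ln is None:
            ln = samples[0].waveforms[m].length if m in samples[0].waveforms else None
        if ln is None:
            raise KeyError(f"modality {m!r} absent from registry and first sample")
        lengths[m] = ln

    rows = []
    for s in samples:
        s.require(spec.modality_order)
        parts = []
        for m in spec.modality_order:
            rec = s.waveforms[m]
            if rec.length != lengths[m]:
                raise ValueError(
                    f"sample {s.sample_id!r}: {m} has length {rec.length}, expected {lengths[m]}"
                )
            parts.append(rec.values / spec.scale_factors[m])
        if spec.strategy == "channel_stack":
            L = {lengths[m] for m in spec.modality_order}
            if len(L) != 1:
                raise ValueError(f"channel_stack requires equal lengths, got {lengths}")
            rows.append(np.stack(parts, axis=-1))  # (L, C)
        else:
            rows.append(np.concatenate(parts))  # (T,)
    data = np.stack(rows)
    return FusedTensor([s.sample_id for s in samples], data, spec, lengths)


def unfuse(fused: FusedTensor) -> dict[str, np.ndarray]:
    """Invert :func:`fuse` back to per-modality *scaled* waveform arrays."""
    out: dict[str, np.ndarray] = {}
    for m, idx in fused.modality_slices().items():
        out[m] = np.asarray(fused.data[idx])
    return out


# ---------------------------------------------------------------------------
# IO: wide waveform tables and split manifests


def write_waveform_table(samples: Sequence[MultimodalSample], path) -> None:
    """Wide TSV: sample_id, modality, v0..v{L-1} (ragged lengths padded never;
    one row per (sample, modality) with that modality's own length)."""
    rows = []
    for s in samples:
        for m, rec in s.waveforms.items():
            rows.append((s.sample_id, m, rec.values))
    max_len = max(r[2].size for r in rows)
    with open(path, "w") as fh:
        cols = "\t".join(f"v{i}" for i in range(max_len))
        fh.write(f"sample_id\tmodality\t{cols}\n")
        for sid, m, vals in rows:
            body = "\t".join(repr(float(v)) for v in vals)
            pad = "\t" * (max_len - vals.size)
            fh.write(f"{sid}\t{m}\t{body}{pad}\n")


def read_waveform_table(path, registry: Mapping[str, int] = DEFAULT_REGISTRY,
                        ) -> list[MultimodalSample]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     float_precision="round_trip")
    value_cols = [c for c in df.columns if c.startswith("v")]
    by_sample: dict[str, dict[str, WaveformRecord]] = {}
    for _, row in df.iterrows():
        vals = row[value_cols].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        rec = WaveformRecord(row["sample_id"], row["modality"], vals)
        rec.validate(registry)
        by_sample.setdefault(row["sample_id"], {})[row["modality"]] = rec
    return [MultimodalSample(sid, wf) for sid, wf in by_sample.items()]


def write_split_manifest(samples: Sequence[MultimodalSample], path) -> None:
    pd.DataFrame(
        {"sample_id": [s.sample_id for s in samples], "split": [s.split for s in samples]}
    ).to_csv(path, sep="\t", index=False)


def read_split_manifest(path) -> dict[str, Split]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["split"]))
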