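"""Raw condition blocks -> analysis-ready segments.

The pipeline is DC removal, average reference, then edge trimming and
concatenation of the per-condition clips: five 24-s action clips trimmed
by 2 s at both ends give five 20-s epochs, i.e. a single 100-s segment
per condition; a 120-s resting block trimmed by 10 s gives the same.
"""

from __future__ import annotations

import numpy as np

from .core import (
    ConditionSegment,
    InconsistentInputError,
    InvalidInputError,
    InvalidTrimError,
    Recording,
)


def remove_dc(rec: Recording) -> Recording:
    """Subtract each channel's temporal mean."""
    if rec.n_samples == 0 or rec.n_channels == 0:
        raise InvalidInputError("empty recording")
    out = rec.copy()
    out.data -= out.data.mean(axis=1, keepdims=True)
    return out


def average_reference(rec: Recording) -> Recording:
    """Re-reference so the mean across channels is zero at every sample.

    Idempotent; requires at least two channels.
    """
    if rec.n_channels < 2:
        raise InvalidInputError("average reference needs >= 2 channels")
    out = rec.copy()
    out.data -= out.data.mean(axis=0, keepdims=True)
    return out


def split_clips(rec: Recording, clip_seconds: float) -> list[Recording]:
    """Slice a multi-clip recording into its contiguous clip blocks."""
    clip_len = int(round(clip_seconds * rec.fs))
    if clip_len < 1 or rec.n_samples % clip_len != 0:
        raise InvalidInputError(
            f"{rec.n_samples} samples do not divide into {clip_seconds}-s clips"
        )
    blocks = []
    for i in range(rec.n_samples // clip_len):
        b = Recording(
            rec.data[:, i * clip_len:(i + 1) * clip_len].copy(),
            rec.fs, list(rec.ch_names), rec.condition, rec.subject, rec.session,
        )
        blocks.append(b)
    return blocks


def trim_and_concatenate(
    blocks: list[Recording], trim_seconds: float
) -> ConditionSegment:
    """Drop trim_seconds from both ends of every block, then concatenate.

    Trim is converted to samples by rounding to the nearest sample.
    Provenance stores, per block, the half-open [start, stop) sample range
    kept from the original block.
    """
    if not blocks:
        raise InvalidInputError("no blocks to concatenate")
    fs = blocks[0].fs
    ch_names = blocks[0].ch_names
    trim = int(round(trim_seconds * fs))
    if trim < 0:
        raise InvalidTrimError("trim must be non-negative")
    parts, provenance = [], []
    for i, b in enumerate(blocks):
        if b.fs != fs or b.ch_names != ch_names:
            raise InconsistentInputError("blocks differ in fs or channel set")
        if b.n_samples <= 2 * trim:
            raise InvalidTrimError(
                f"block {i} of {b.n_samples} samples <= 2 x trim ({trim})"
            )
        stop = b.n_samples - trim
        parts.append(b.data[:, trim:stop])
        provenance.append((i, trim, stop))
    first = blocks[0]
    return ConditionSegment(
        np.concatenate(parts, axis=1), fs, list(ch_names),
        condition=first.condition, subject=first.subject, session=first.session,
        provenance=provenance,
    )


def preprocess_condition(
    rec: Recording,
    clip_seconds: float | None,
    trim_seconds: float,
) -> ConditionSegment:
    """Full preprocessing of one condition recording.

    clip_seconds=None treats the recording as a single block (resting
    conditions); otherwise it is split into clips before trimming.
    """
    rec = average_reference(remove_dc(rec))
    if clip_seconds is None:
        blocks = [rec]
    else:
        blocks = split_clips(rec, clip_seconds)
    return trim_and_concatenate(blocks, trim_seconds)
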