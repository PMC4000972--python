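"""End-to-end glue: volumes -> gist features -> labeled clips -> report."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .evaluation import LabeledClip
from .gabor3d import FilterBank, build_default_bank
from .gist3d import extract_gist
from .synthetic_videos import SynthClip
from .video_io import LABEL_TO_SIGN

__all__ = ["features_from_clips", "labeled_clips_from_table"]


def features_from_clips(
    clips,
    bank: FilterBank | None = None,
) -> list[LabeledClip]:
    """Extract the gist feature of every clip, keeping labels and provenance.

    Accepts any iterable of clips (e.g. :func:`~gaborgist.iter_cohort`), so
    volumes can be generated, featurized and discarded one at a time.
    """
    bank = bank or build_default_bank()
    out = []
    for clip in clips:
        feat = extract_gist(clip.volume, bank)
        out.append(
            LabeledClip(
                clip_id=clip.volume.clip_id,
                patient_id=clip.volume.patient_id,
                feature=feat.values,
                label=LABEL_TO_SIGN[clip.annotation.label],
            )
        )
    return out


def labeled_clips_from_table(df) -> list[LabeledClip]:
    """Build labeled clips from a feature table DataFrame (see gist3d)."""
    fcols = sorted(
        (c for c in df.columns if c.startswith("f") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    return [
        LabeledClip(
            clip_id=str(row["clip_id"]),
            patient_id=str(row["patient_id"]),
            feature=np.asarray([row[c] for c in fcols], dtype=float),
            label=LABEL_TO_SIGN[str(row["label"]).strip().lower()],
        )
        for _, row in df.iterrows()
    ]
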