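"""Patch extraction and section-level dataset splitting.

Sections are tiled on a non-overlapping grid anchored at (0, 0); a tile is
retained when at least ``min_tissue_frac`` of its pixels lie inside the tissue
mask.  Splitting is always by whole section so no patch from one biopsy leaks
between training and evaluation splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ChannelStats, LabelMap, MultimodalStack, ParameterError

__all__ = [
    "Patch",
    "DatasetManifest",
    "extract_patches",
    "split_sections",
    "class_pixel_summary",
]

log = logging.getLogger(__name__)

TISSUE_CLASSES = (1, 2, 3)


@dataclass
class Patch:
    """One non-overlapping window of the analysis stack.

    ``mask`` is the tissue-mask window; ``tissue_frac`` is its mean.  Channels
    are kept raw (unstandardized) — standardization statistics travel with the
    training run, not the patch.
    """

    channels: np.ndarray  # (C, P, P) float32
    labels: np.ndarray  # (P, P) uint8, values {0..3}
    mask: np.ndarray  # (P, P) bool
    section_id: str
    origin: tuple[int, int]  # (row, col), multiples of the patch size
    tissue_frac: float

    @property
    def size(self) -> int:
        return self.labels.shape[0]


@dataclass
class DatasetManifest:
    """Bookkeeping for a patch dataset: per-patch provenance and split."""

    entries: pd.DataFrame  # section_id, split, origin_row, origin_col, tissue_frac
    patches: dict[str, list[Patch]] = field(default_factory=dict)  # section_id -> patches
    stats: ChannelStats | None = None

    def section_ids(self, split: str) -> list[str]:
        sel = self.entries[self.entries["split"] == split]
        return sorted(sel["section_id"].unique())

    def split_patches(self, split: str) -> list[Patch]:
        out = []
        for sid in self.section_ids(split):
            out.extend(self.patches.get(sid, []))
        return out

    def validate(self) -> None:
        per_section = self.entries.groupby("section_id")["split"].nunique()
        if (per_section > 1).any():
            bad = per_section[per_section > 1].index.tolist()
            raise ParameterError(f"sections in more than one split: {bad}")


def extract_patches(
    stack: MultimodalStack,
    labels: LabelMap | None = None,
    patch_size: int = 256,
    min_tissue_frac: float = 0.5,
) -> list[Patch]:
    """Tile a section into retained patches (row-major, deterministic order).

    Partial tiles at the bottom/right edges are discarded, matching the
    non-overlapping grid; a patch larger than the section yields an empty
    list with a warning rather than an error.
    """
    h, w = stack.grid_shape
    if labels is not None and labels.shape != (h, w):
        raise ParameterError("labels and stack grid mismatch")
    if patch_size > h or patch_size > w:
        log.warning(
            "patch_size %d exceeds section %s grid %s; no patches extracted",
            patch_size, stack.section_id, (h, w),
        )
        return []
    lab = labels.labels if labels is not None else np.zeros((h, w), dtype=np.uint8)
    out: list[Patch] = []
    for r0 in range(0, h - patch_size + 1, patch_size):
        for c0 in range(0, w - patch_size + 1, patch_size):
            win = (slice(r0, r0 + patch_size), slice(c0, c0 + patch_size))
            m = stack.tissue_mask[win]
            frac = float(m.mean())
            if frac < min_tissue_frac:
                continue
            out.append(
                Patch(
                    channels=stack.channels[(slice(None),) + win].copy(),
                    labels=lab[win].copy(),
                    mask=m.copy(),
                    section_id=stack.section_id,
                    origin=(r0, c0),
                    tissue_frac=frac,
                )
            )
    return out


def split_sections(
    section_ids: list[str],
    counts: tuple[int, ...] | None = None,
    fractions: tuple[float, ...] | None = None,
    seed: int = 0,
    split_names: tuple[str, ...] | None = None,
) -> dict[str, list[str]]:
    """Partition sections into disjoint splits, reproducibly for a seed.

    ``counts`` gives exact sizes (e.g. (20, 3) for the two-way train /
    held-out design, or (8, 2, 2) for train/val/test); ``fractions`` gives
    proportions instead.  Unnamed splits default to train/val/test (or
    train/test for a two-way split).
    """
    ids = list(section_ids)
    if len(ids) < 3:
        raise ParameterError("need at least 3 sections to split")
    if counts is None and fractions is None:
        raise ParameterError("provide counts or fractions")
    if counts is None:
        total = sum(fractions)
        counts = tuple(int(round(f / total * len(ids))) for f in fractions[:-1])
        counts = counts + (len(ids) - sum(counts),)
    if sum(counts) > len(ids):
        raise ParameterError(f"requested {sum(counts)} sections, only {len(ids)} available")
    if split_names is None:
        split_names = ("train", "test") if len(counts) == 2 else ("train", "val", "test")
    if len(split_names) != len(counts):
        raise ParameterError("split_names and counts length mismatch")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    splits: dict[str, list[str]] = {}
    pos = 0
    for name, n in zip(split_names, counts):
        splits[name] = sorted(order[pos:pos + n])
        pos += n
    return splits


def build_manifest(
    splits: dict[str, list[str]],
    patches_by_section: dict[str, list[Patch]],
    stats: ChannelStats | None = None,
) -> DatasetManifest:
    rows = []
    for split, sids in splits.items():
        for sid in sids:
            for p in patches_by_section.get(sid, []):
                rows.append(
                    {
                        "section_id": sid,
                        "split": split,
                        "origin_row": p.origin[0],
                        "origin_col": p.origin[1],
                        "tissue_frac": p.tissue_frac,
                    }
                )
    entries = pd.DataFrame(
        rows, columns=["section_id", "split", "origin_row", "origin_col", "tissue_frac"]
    )
    manifest = DatasetManifest(entries=entries, patches=dict(patches_by_section), stats=stats)
    manifest.validate()
    return manifest


def class_pixel_summary(manifest: DatasetManifest, split: str) -> dict[int, int]:
    """Per-class pixel counts (classes 1..3; background excluded) for a split."""
    patches = manifest.split_patches(split)
    if not patches:
        log.warning("split %r has no patches; returning zero counts", split)
        return {c: 0 for c in TISSUE_CLASSES}
    counts = np.zeros(4, dtype=np.int64)
    for p in patches:
        counts += np.bincount(p.labels.ravel(), minlength=4)[:4]
    return {c: int(counts[c]) for c in TISSUE_CLASSES}
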