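"""Monte-Carlo multi-patch ensemble scoring of whole fields and participants.

A field is never scored from a single patch: ``rounds`` times (100 by
default), ``k`` patches (4 by default) are drawn uniformly from the field's
filtered patch pool, classified, and their probability vectors averaged; the
field score is the mean over rounds.  Because inference is deterministic per
patch, this equals the average of the per-patch probabilities weighted by how
often each patch was drawn, so the implementation classifies each pooled
patch once and averages cached probabilities over the sampled index sets —
numerically identical to the direct mean-over-rounds-of-mean-over-k, at a
fraction of the cost.

The class probabilities of a field score are the CCCP-score / FL3-score /
NC-score used everywhere downstream; a participant's score is the unweighted
mean of their field scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mitoscore import imaging_io, segpatch
from mitoscore.segpatch import FieldUnusableError

logger = logging.getLogger(__name__)

ROUNDS_DEFAULT = 100


@dataclass
class FieldScore:
    """Per-class probability vector for one whole field."""

    field_id: str
    probabilities: np.ndarray
    class_order: list[str]
    n_rounds: int
    k_patches: int
    pool_size: int

    def score(self, class_label: str) -> float:
        return float(self.probabilities[self.class_order.index(class_label)])

    def as_dict(self) -> dict[str, float]:
        return {f"score_{c}": float(p) for c, p in zip(self.class_order, self.probabilities)}


@dataclass
class ParticipantScore:
    """Unweighted mean of one participant's field scores."""

    participant_id: str
    probabilities: np.ndarray
    class_order: list[str]
    n_fields: int
    group: str | None = None


def _round_seed(seed: int, r: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, r]))


def score_field(
    model,
    image: np.ndarray,
    mask: np.ndarray | segpatch.ForegroundMask,
    rounds: int = ROUNDS_DEFAULT,
    k: int = segpatch.SAMPLE_K_DEFAULT,
    seed: int = 0,
    patch_size: int = segpatch.PATCH_SIZE_DEFAULT,
    stride: int = segpatch.STRIDE_DEFAULT,
    min_fg: float = segpatch.MIN_FG_DEFAULT,
    field_id: str = "",
) -> FieldScore:
    """Monte-Carlo ensemble score of one field.

    ``model`` needs ``predict_batch(list of patch arrays) -> (n, c) probs``
    and ``class_order``.  Per-round RNGs are derived from ``(seed, round)``,
    so rounds are order-independent and the result is deterministic given
    ``seed``.  Raises :class:`FieldUnusableError` when the filtered pool is
    empty.
    """
    if rounds < 1:
        raise ValueError(f"rounds must be >= 1, got {rounds}")
    pool = segpatch.patch_pool(image, mask, patch_size=patch_size, stride=stride, min_fg=min_fg)
    if not pool:
        raise FieldUnusableError(field_id=field_id)
    probs = np.asarray(model.predict_batch([p.pixels for p in pool]), dtype=np.float64)
    indices = list(range(len(pool)))
    acc = np.zeros(probs.shape[1])
    for r in range(rounds):
        chosen = segpatch.sample_patches(indices, k=k, seed=_round_seed(seed, r), field_id=field_id)
        acc += probs[chosen].mean(axis=0)
    return FieldScore(
        field_id=field_id,
        probabilities=acc / rounds,
        class_order=list(model.class_order),
        n_rounds=rounds,
        k_patches=k,
        pool_size=len(pool),
    )


def score_cohort(
    model,
    manifest: pd.DataFrame,
    rounds: int = ROUNDS_DEFAULT,
    k: int = segpatch.SAMPLE_K_DEFAULT,
    seed: int = 0,
    patch_size: int = segpatch.PATCH_SIZE_DEFAULT,
    stride: int = segpatch.STRIDE_DEFAULT,
    min_fg: float = segpatch.MIN_FG_DEFAULT,
    use_manifest_masks: bool = True,
    seg_sigma: float = 8.0,
) -> pd.DataFrame:
    """Score every usable field of a manifest; one row per field.

    Fields are read from ``manifest['path']`` (z-stacks are max-projected),
    percentile-normalized, and masked either by the manifest's ``mask_path``
    (when present and ``use_manifest_masks``) or by the classical foreground
    segmenter.  Fields with empty patch pools are skipped and logged; zero
    usable fields is an error.
    """
    rows = []
    n_skipped = 0
    for i, rec in enumerate(manifest.to_dict("records")):
        image = imaging_io.max_project(imaging_io.read_field(rec["path"]))
        image = imaging_io.normalize_percentile(image)
        if use_manifest_masks and rec.get("mask_path"):
            mask = imaging_io.read_field(rec["mask_path"]) > 0
        else:
            mask = segpatch.segment_foreground(image, sigma=seg_sigma).mask
        try:
            fs = score_field(
                model, image, mask, rounds=rounds, k=k,
                seed=int(np.random.SeedSequence([seed & 0x7FFFFFFF, i]).generate_state(1)[0] & 0x7FFFFFFF),
                patch_size=patch_size, stride=stride, min_fg=min_fg,
                field_id=str(rec["field_id"]),
            )
        except FieldUnusableError:
            logger.warning("skipping field %s: empty filtered patch pool", rec["field_id"])
            n_skipped += 1
            continue
        row = {
            "field_id": rec["field_id"],
            "participant_id": rec.get("participant_id", ""),
            "label": rec.get("label", ""),
            "experiment_id": rec.get("experiment_id", ""),
            **fs.as_dict(),
            "n_rounds": fs.n_rounds,
            "pool_size": fs.pool_size,
        }
        if "group" in rec:
            row["group"] = rec["group"]
        rows.append(row)
    if not rows:
        raise RuntimeError(f"no usable fields in manifest ({n_skipped} skipped)")
    if n_skipped:
        logger.info("scored %d fields, skipped %d", len(rows), n_skipped)
    return pd.DataFrame(rows)


def score_participant(field_scores: list[FieldScore], participant_id: str = "", group: str | None = None) -> ParticipantScore:
    """Unweighted mean of a participant's field-score vectors."""
    if not field_scores:
        raise ValueError("participant has no field scores")
    order = field_scores[0].class_order
    if any(fs.class_order != order for fs in field_scores):
        raise ValueError("inconsistent class orders across field scores")
    probs = np.mean([fs.probabilities for fs in field_scores], axis=0)
    return ParticipantScore(
        participant_id=participant_id,
        probabilities=probs,
        class_order=list(order),
        n_fields=len(field_scores),
        group=group,
    )


def participant_table(score_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a field-score table to one row per participant (unweighted
    mean of field scores; fields-as-replicates analyses can keep using the
    field table directly)."""
    score_cols = [c for c in score_table.columns if c.startswith("score_")]
    keys = ["participant_id"] + (["group"] if "group" in score_table.columns else [])
    agg = score_table.groupby(keys, as_index=False)[score_cols].mean()
    counts = score_table.groupby(keys, as_index=False).size().rename(columns={"size": "n_fields"})
    return agg.merge(counts, on=keys)
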