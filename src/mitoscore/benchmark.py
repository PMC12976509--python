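"""Desk-scale synthetic benchmarks of the full scoring pipeline.

These functions run the whole method — simulate fields, segment foreground,
tile/filter patches, train the patch classifier, Monte-Carlo score held-out
fields — at sizes a single CPU handles in minutes: 512-px fields, 30 fields
per condition, 10 training epochs, 64-px working patches.  They are the
package's own evidence that the pipeline recovers the generating morphology:

* grouped held-out classification of the three synthetic conditions
  (:func:`end_to_end_benchmark`);
* dose-response monotonicity of the fusion-score along the continuum
  (:func:`continuum_monotonicity`);
* participant-level discrimination of a mildly-hyperfused cohort
  (:func:`cohort_fusion_auc`);
* Monte-Carlo convergence of the field score (:func:`mc_convergence`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mitoscore import cnn, evalstats, mc_scoring, segpatch, simcell
from mitoscore.imaging_io import normalize_percentile
from mitoscore.simcell import _CLASS_BANDS, _child_seed


@dataclass
class SyntheticField:
    """One in-memory field ready for patching: normalized image + mask."""

    field_id: str
    image: np.ndarray
    mask: np.ndarray
    label: str
    phi: float
    experiment_id: str
    participant_id: str = ""


def make_field_set(
    seed: int,
    n_per_class: int = 30,
    field_size_px: int = 512,
    noise_level: float = 0.05,
    n_experiments: int = 5,
    phi_jitter: float = 0.08,
) -> list[SyntheticField]:
    """The default three-condition study set: fission-like / normal /
    fusion-like fields with round-robin acquisition batches, percentile-
    normalized, foreground-segmented with the classical segmenter."""
    specs = simcell.default_class_specs(field_size_px, noise_level)
    fields: list[SyntheticField] = []
    for ci, (label, spec) in enumerate(sorted(specs.items())):
        lo, hi = _CLASS_BANDS[label]
        for i in range(n_per_class):
            child = _child_seed(seed, ci, i)
            jrng = np.random.default_rng(child)
            phi_i = float(np.clip(spec.phi + jrng.uniform(-phi_jitter, phi_jitter), lo, hi))
            sim = simcell.simulate_field(dataclasses.replace(spec, phi=phi_i, seed=child))
            image = normalize_percentile(sim.image)
            mask = segpatch.segment_foreground(image).mask
            fields.append(
                SyntheticField(
                    field_id=f"{label}_{i:04d}",
                    image=image,
                    mask=mask,
                    label=label,
                    phi=phi_i,
                    experiment_id=f"E{i % n_experiments}",
                )
            )
    return fields


def fields_manifest(fields: list[SyntheticField]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "field_id": f.field_id,
                "label": f.label,
                "experiment_id": f.experiment_id,
                "participant_id": f.participant_id,
                "phi": f.phi,
            }
            for f in fields
        ]
    )


def training_patches(
    fields: list[SyntheticField],
    classes: list[str],
    seed: int,
    max_patches_per_field: int = 32,
    patch_size: int = 112,
    stride: int = 56,
    min_fg: float = 0.5,
) -> list[tuple[np.ndarray, str]]:
    """Filtered-pool patches from training fields, capped per field.

    Training uses a denser tiling (stride 56, half-overlap) than scoring:
    desk-scale 512-px fields yield only a handful of non-overlapping
    foreground windows, and the classifier needs per-field patch volume
    comparable to what full-resolution fields provide at the standard
    stride."""
    out: list[tuple[np.ndarray, str]] = []
    for i, f in enumerate(fields):
        if f.label not in classes:
            continue
        pool = segpatch.patch_pool(f.image, f.mask, patch_size, stride, min_fg)
        if not pool:
            continue
        rng = np.random.default_rng(_child_seed(seed, 0xA11, i))
        take = min(max_patches_per_field, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        out.extend((pool[j].pixels, f.label) for j in idx)
    return out


def train_task_model(
    fields: list[SyntheticField],
    task: str,
    seed: int,
    epochs: int = 10,
    out_size: int = 64,
    lr: float = 2e-3,
    batch_size: int = 32,
    channels: tuple[int, int] = (8, 16),
    max_patches_per_field: int = 32,
) -> cnn.TrainedModel:
    classes = cnn.TASKS[task]
    patches = training_patches(fields, classes, seed, max_patches_per_field)
    config = cnn.TrainConfig(
        task=task,
        epochs=epochs,
        lr=lr,
        batch_size=batch_size,
        channels=channels,
        seed=seed,
        augment=cnn.AugmentSpec(out_size=out_size),
    )
    return cnn.train(patches, config)


def score_fields(
    model: cnn.TrainedModel,
    fields: list[SyntheticField],
    rounds: int = 100,
    k: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    rows = []
    for i, f in enumerate(fields):
        fs = mc_scoring.score_field(
            model, f.image, f.mask, rounds=rounds, k=k,
            seed=_child_seed(seed, 0x5C0, i), field_id=f.field_id,
        )
        rows.append(
            {
                "field_id": f.field_id,
                "label": f.label,
                "phi": f.phi,
                "participant_id": f.participant_id,
                **fs.as_dict(),
            }
        )
    return pd.DataFrame(rows)


def grouped_split(fields: list[SyntheticField], seed: int, n_folds: int = 5, test_folds: tuple[int, ...] = (0, 1)):
    """Grouped train/test split by experiment; test folds are held out."""
    manifest = fields_manifest(fields)
    folds = evalstats.make_grouped_folds(manifest, n_folds=n_folds, seed=seed)
    test_set = {e for tf in test_folds for e in folds.test_experiments(tf)}
    train = [f for f in fields if f.experiment_id not in test_set]
    test = [f for f in fields if f.experiment_id in test_set]
    return train, test, folds


def end_to_end_benchmark(seed: int, n_per_class: int = 30, epochs: int = 10, rounds: int = 100) -> dict:
    """Full desk-scale run: returns held-out fission-vs-normal field ROC-AUC
    (binary CCCP-NC model) and held-out three-class field accuracy
    (CCCP-FL3-NC model), plus the trained three-class model for reuse."""
    fields = make_field_set(seed, n_per_class=n_per_class)
    train_fields, test_fields, _ = grouped_split(fields, seed)

    binary = train_task_model(train_fields, "CCCP-NC", seed, epochs=epochs)
    bin_test = [f for f in test_fields if f.label in ("CCCP", "NC")]
    bin_scores = score_fields(binary, bin_test, rounds=rounds, seed=seed)
    roc = evalstats.roc_auc(bin_scores["score_CCCP"], bin_scores["label"], positive_label="CCCP")

    three = train_task_model(train_fields, "CCCP-FL3-NC", seed, epochs=epochs)
    tri_scores = score_fields(three, test_fields, rounds=rounds, seed=seed)
    score_cols = [f"score_{c}" for c in three.class_order]
    pred = tri_scores[score_cols].to_numpy().argmax(axis=1)
    pred_labels = [three.class_order[i] for i in pred]
    accuracy = float((np.asarray(pred_labels) == tri_scores["label"].to_numpy()).mean())

    return {
        "fission_vs_normal_auc": roc.auc,
        "three_class_accuracy": accuracy,
        "n_test_fields": len(test_fields),
        "binary_model": binary,
        "three_class_model": three,
    }


def continuum_monotonicity(
    model: cnn.TrainedModel,
    seed: int,
    phis: tuple[float, ...] = (0.5, 0.625, 0.75, 0.875, 1.0),
    n_per_level: int = 10,
    field_size_px: int = 512,
) -> dict:
    """Dose-response check: mean fusion-score per continuum level vs phi.

    Emulates a graded hyperfusion-inducing treatment by rendering fields at
    increasing phi and scoring them; returns the per-level mean FL3-scores
    and their Spearman correlation with phi.
    """
    base = simcell.MorphologySpec(phi=0.5, field_size_px=field_size_px)
    level_means = []
    for li, phi in enumerate(phis):
        scores = []
        for i in range(n_per_level):
            child = _child_seed(seed, 0xD05E, li, i)
            sim = simcell.simulate_field(dataclasses.replace(base, phi=phi, seed=child))
            image = normalize_percentile(sim.image)
            mask = segpatch.segment_foreground(image).mask
            fs = mc_scoring.score_field(model, image, mask, rounds=100, k=4, seed=child)
            scores.append(fs.score("FL3"))
        level_means.append(float(np.mean(scores)))
    rho = float(stats.spearmanr(phis, level_means).statistic)
    return {"phis": list(phis), "mean_fusion_scores": level_means, "spearman_rho": rho}


def cohort_fusion_auc(
    model: cnn.TrainedModel,
    seed: int,
    n_participants: int = 8,
    n_fields_per_participant: int = 5,
    phi_positive: float = 0.8,
    phi_reference: float = 0.5,
    field_size_px: int = 512,
) -> dict:
    """Participant-level ROC of the mean fusion-score: a cohort whose
    positive participants' fields are mildly hyperfused (phi=0.8) versus
    reference participants at normal morphology (phi=0.5)."""
    base = simcell.MorphologySpec(phi=0.5, field_size_px=field_size_px)
    rows = []
    for gi, (group, phi) in enumerate((("positive", phi_positive), ("reference", phi_reference))):
        for p in range(n_participants):
            field_scores = []
            for i in range(n_fields_per_participant):
                child = _child_seed(seed, 0xC040, gi, p, i)
                sim = simcell.simulate_field(dataclasses.replace(base, phi=phi, seed=child))
                image = normalize_percentile(sim.image)
                mask = segpatch.segment_foreground(image).mask
                fs = mc_scoring.score_field(model, image, mask, rounds=100, k=4, seed=child)
                field_scores.append(fs)
            ps = mc_scoring.score_participant(field_scores, participant_id=f"{group}_{p}", group=group)
            rows.append({"participant_id": ps.participant_id, "group": group, "score_FL3": ps.probabilities[model.class_order.index("FL3")]})
    table = pd.DataFrame(rows)
    roc = evalstats.roc_auc(table["score_FL3"], table["group"], positive_label="positive")
    return {"auc": roc.auc, "participants": table}


class _IntensityScorer:
    """Toy deterministic patch scorer (mean-intensity logistic); exercises
    the Monte-Carlo machinery without a trained network."""

    class_order = ["bright", "dark"]

    def predict_batch(self, patches):
        p = np.array([np.clip(np.mean(x) * 4.0, 0.02, 0.98) for x in patches])
        return np.column_stack([p, 1.0 - p])


def mc_convergence(seed: int, rounds_levels: tuple[int, ...] = (1, 10, 100), n_seeds: int = 40) -> dict:
    """Monte-Carlo standard-error scaling and the exact sampling oracle.

    On one synthetic field with a deterministic toy scorer: (a) the SD of the
    field score across independent sampling seeds should scale ~1/sqrt(rounds)
    (log-log slope -0.5); (b) on a pool truncated to 8 patches, enumeration of
    all C(8,4) subsets shows the expected field score equals the pool-mean
    probability, which the empirical mean over seeds approaches.
    """
    from itertools import combinations

    sim = simcell.simulate_field(simcell.MorphologySpec(phi=0.5, seed=_child_seed(seed, 0x3C)))
    image = normalize_percentile(sim.image)
    mask = segpatch.segment_foreground(image).mask
    model = _IntensityScorer()

    sds = []
    for rounds in rounds_levels:
        vals = [
            mc_scoring.score_field(
                model, image, mask, rounds=rounds, k=4, seed=_child_seed(seed, 0x3D, rounds, s)
            ).probabilities[0]
            for s in range(n_seeds)
        ]
        sds.append(float(np.std(vals)))
    slope = float(np.polyfit(np.log10(rounds_levels), np.log10(sds), 1)[0])

    # exact enumeration oracle on a small pool
    pool = segpatch.patch_pool(image, mask)[:8]
    probs = model.predict_batch([p.pixels for p in pool])[:, 0]
    subsets = list(combinations(range(len(pool)), 4))
    enum_expectation = float(np.mean([probs[list(s)].mean() for s in subsets]))
    pool_mean = float(probs.mean())
    empirical = float(
        np.mean(
            [
                _score_pool_subset(model, pool, seed=_child_seed(seed, 0x3E, s))
                for s in range(200)
            ]
        )
    )
    return {
        "rounds_levels": list(rounds_levels),
        "sds": sds,
        "loglog_slope": slope,
        "enum_expectation": enum_expectation,
        "pool_mean": pool_mean,
        "empirical_mean": empirical,
    }


def _score_pool_subset(model, pool, seed: int, rounds: int = 4, k: int = 4) -> float:
    probs = model.predict_batch([p.pixels for p in pool])
    acc = 0.0
    for r in range(rounds):
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, r]))
        idx = rng.choice(len(pool), size=k, replace=False)
        acc += probs[idx, 0].mean()
    return acc / rounds
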