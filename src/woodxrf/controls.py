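"""Randomized-label control against memorization and data leakage.

The control retrains the identical architecture and protocol on labels
drawn independently of the spectra — a vocabulary of arbitrary words with
no relation to the data.  A healthy pipeline scores near the majority-label
frequency on the control and far above it on the true labels; a control
that performs well indicates memorization capacity or leakage of validation
rows into training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import model as model_mod
from .errors import ConfigurationError
from .evaluate import EvaluationReport, evaluate
from .preprocess import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = ["ControlResult", "randomize_labels", "run_control"]

#: Repository policy, stated in every report: the control passes if its
#: validation accuracy is within this many percentage points above the
#: majority-label frequency ...
PASS_TOLERANCE_PCT = 5.0
#: ... and the true-label model beats the control by at least this margin.
PASS_MARGIN_PCT = 30.0


@dataclass
class ControlResult:
    """Outcome of one randomized-label control run."""

    reference_report: EvaluationReport
    control_report: EvaluationReport
    k: int
    majority_label_frequency_pct: float
    verdict: str  # "pass" or "fail"
    diagnostic: str
    tolerance_pct: float = PASS_TOLERANCE_PCT
    margin_pct: float = PASS_MARGIN_PCT

    def summary(self) -> str:
        return (
            f"verdict={self.verdict} ({self.diagnostic})\n"
            f"  reference: {self.reference_report.summary()}\n"
            f"  control:   {self.control_report.summary()}\n"
            f"  K={self.k}, majority label {self.majority_label_frequency_pct:.2f}%, "
            f"tolerance +{self.tolerance_pct:.0f} pts, margin {self.margin_pct:.0f} pts"
        )


def _control_vocabulary(k: int) -> list[str]:
    return [f"word_{i:02d}" for i in range(k)]


def randomize_labels(dataset: LabeledDataset, k: int = 29,
                     label_weights=None, seed: int = 0) -> LabeledDataset:
    """Replace labels with independent draws from a k-word vocabulary.

    ``label_weights`` may be ``None`` (uneven weights drawn from a flat
    Dirichlet — the mechanism behind a majority-collapse control),
    ``"uniform"``, or an explicit probability vector of length k.  Features
    and sample groups are untouched.
    """
    if k < 2:
        raise ConfigurationError("control vocabulary needs at least 2 labels")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0DE)))
    if label_weights is None:
        weights = rng.dirichlet(np.ones(k))
    elif isinstance(label_weights, str) and label_weights == "uniform":
        weights = np.full(k, 1.0 / k)
    else:
        weights = np.asarray(label_weights, dtype=float)
        if len(weights) != k or np.any(weights < 0):
            raise ConfigurationError("label_weights must be k non-negative values")
        if not np.isclose(weights.sum(), 1.0):
            raise ConfigurationError("label_weights must sum to 1")
        if np.any(weights >= 1.0 - 1e-12):
            raise ConfigurationError("degenerate label weights: one class has mass 1")
    vocab = _control_vocabulary(k)
    labels = rng.choice(vocab, size=len(dataset), p=weights)
    return LabeledDataset(
        features=dataset.features,
        labels=labels,
        groups=dataset.groups,
        grid=dataset.grid,
        vocabulary=vocab,
    )


def _train_and_report(dataset: LabeledDataset, config: model_mod.CNNConfig,
                      leak_validation: bool = False):
    train_set, val_set = model_mod.split(
        dataset, config.val_fraction, config.split_strategy, config.seed
    )
    if leak_validation:
        # deliberate-bug switch for testing the leakage detector: the
        # validation rows are also shown to the optimizer
        merged_rows = np.arange(len(dataset))
        train_set = dataset.subset(merged_rows)
    classifier = model_mod.build(
        config, dataset.grid.n_bins, dataset.n_classes,
        grid=dataset.grid, vocabulary=dataset.vocabulary,
    )
    classifier, _ = model_mod.train(classifier, train_set, val_set, config)
    _, report = evaluate(classifier, val_set)
    return classifier, report


def run_control(dataset: LabeledDataset, config: model_mod.CNNConfig,
                k: int = 29, seed: int = 0, label_weights=None,
                leak_validation: bool = False,
                tolerance_pct: float = PASS_TOLERANCE_PCT,
                margin_pct: float = PASS_MARGIN_PCT) -> ControlResult:
    """Train reference (true labels) and control (random labels) models.

    Both runs use the identical architecture, split protocol and epoch
    budget.  ``leak_validation`` deliberately includes validation rows in
    the control's training set, which should trip the verdict — it exists so
    the leakage detector itself can be tested.
    """
    _, ref_report = _train_and_report(dataset, config)
    randomized = randomize_labels(dataset, k=k, label_weights=label_weights, seed=seed)
    counts = {}
    for lab in randomized.labels.tolist():
        counts[lab] = counts.get(lab, 0) + 1
    majority_pct = 100.0 * max(counts.values()) / len(randomized)
    _, ctl_report = _train_and_report(randomized, config, leak_validation=leak_validation)

    ctl_acc = ctl_report.accuracy_pct
    ref_acc = ref_report.accuracy_pct
    ref_chance_pct = 100.0 / dataset.n_classes
    near_chance = ctl_acc <= majority_pct + tolerance_pct
    separated = ref_acc - ctl_acc >= margin_pct
    if not near_chance:
        verdict = "fail"
        diagnostic = (
            f"control accuracy {ctl_acc:.1f}% exceeds majority frequency "
            f"{majority_pct:.1f}% + {tolerance_pct:.0f} pts: possible "
            "memorization or data leakage"
        )
    elif ref_acc <= ref_chance_pct + tolerance_pct:
        verdict = "fail"
        diagnostic = (
            f"no signal: reference accuracy {ref_acc:.1f}% is at its own "
            f"chance level ({ref_chance_pct:.1f}%)"
        )
    elif not separated:
        verdict = "fail"
        diagnostic = (
            f"no signal: reference accuracy {ref_acc:.1f}% is within "
            f"{margin_pct:.0f} pts of the control ({ctl_acc:.1f}%)"
        )
    else:
        verdict, diagnostic = "pass", "control at chance, reference well above"
    logger.info("control verdict: %s (%s)", verdict, diagnostic)
    return ControlResult(
        reference_report=ref_report,
        control_report=ctl_report,
        k=k,
        majority_label_frequency_pct=majority_pct,
        verdict=verdict,
        diagnostic=diagnostic,
        tolerance_pct=tolerance_pct,
        margin_pct=margin_pct,
    )
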