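"""Validation of computational calls against mutagenesis labels.

Computational and experimental binding/non-binding calls are compared only
on experimentally annotated residues (mutagenesis cannot score the rest).
The four cells are: TP — binding in both; FP — computational binding but
experimental non-binding; TN — non-binding in both; FN — experimental
binding missed by computation.  The scores are

    PREC = TP / (TP + FP)        REC = TP / (TP + FN)

True negatives never enter either score: mutagenesis panels are designed to
probe binding residues, so the pool of potential TNs is tiny and
uninformative.  When TP = 0 both scores are reported as 0.0 (with a
``degenerate`` flag when the denominator is also zero).  Display strings are
truncated to two decimals (4/6 -> "0.66"); full-precision values are kept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

from .classification import BINDING, NON_BINDING, ResidueCallSet
from .mutagenesis import ExperimentalCallSet
from .persistency import truncate_display
from .structure_io import Residue


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    members: dict[str, list[Residue]] = field(default_factory=dict)

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ValidationScores:
    precision: float
    recall: float
    precision_degenerate: bool = False
    recall_degenerate: bool = False

    @property
    def display(self) -> dict[str, str]:
        return {
            "precision": truncate_display(self.precision),
            "recall": truncate_display(self.recall),
        }


def confusion(comp: ResidueCallSet, exp: ExperimentalCallSet) -> ConfusionMatrix:
    """Confusion matrix over the experimentally annotated residues.

    Residues annotated experimentally but absent from the computational call
    set trigger a warning and are treated as computational non-binding.
    """
    cm = ConfusionMatrix(members={"tp": [], "fp": [], "tn": [], "fn": []})
    for res in sorted(exp.calls, key=lambda r: (r[0], r[1])):
        exp_call = exp.calls[res]
        if res not in comp.calls:
            warnings.warn(
                f"residue {res} annotated experimentally but absent from "
                "computational calls; treated as computational non-binding",
                stacklevel=2,
            )
            comp_call = NON_BINDING
        else:
            comp_call = comp.calls[res]
        if exp_call == BINDING and comp_call == BINDING:
            cm.tp += 1
            cm.members["tp"].append(res)
        elif exp_call == NON_BINDING and comp_call == BINDING:
            cm.fp += 1
            cm.members["fp"].append(res)
        elif exp_call == NON_BINDING and comp_call == NON_BINDING:
            cm.tn += 1
            cm.members["tn"].append(res)
        else:
            cm.fn += 1
            cm.members["fn"].append(res)
    return cm


def precision_recall(cm: ConfusionMatrix) -> ValidationScores:
    """Precision and recall from a confusion matrix.

    Zero TP yields 0.0 for both scores; a zero denominator additionally sets
    the corresponding degenerate flag.
    """
    prec_den = cm.tp + cm.fp
    rec_den = cm.tp + cm.fn
    return ValidationScores(
        precision=cm.tp / prec_den if prec_den else 0.0,
        recall=cm.tp / rec_den if rec_den else 0.0,
        precision_degenerate=prec_den == 0,
        recall_degenerate=rec_den == 0,
    )


def validation_report(
    comp: ResidueCallSet, exp: ExperimentalCallSet, label: str = ""
) -> dict:
    """JSON-serialisable report: confusion members + scores (full & display)."""
    cm = confusion(comp, exp)
    scores = precision_recall(cm)
    return {
        "label": label,
        "mode": comp.mode,
        "thresholds": comp.provenance,
        "confusion": {
            "tp": cm.tp,
            "fp": cm.fp,
            "tn": cm.tn,
            "fn": cm.fn,
            "members": {
                k: [f"{c}{n}" for c, n in v] for k, v in cm.members.items()
            },
        },
        "precision": scores.precision,
        "recall": scores.recall,
        "precision_display": scores.display["precision"],
        "recall_display": scores.display["recall"],
        "degenerate": {
            "precision": scores.precision_degenerate,
            "recall": scores.recall_degenerate,
        },
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
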