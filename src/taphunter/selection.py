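"""Truncation analysis: rank position-subset encodings by cross-validated AROC.

The analysis enumerates candidate residue-position subsets, cross-validates
an identically configured SVM on each (with identical fold partitions, so
ranking differences are attributable to the encoding alone), and selects the
subset with the best CV AROC. Ties break toward higher CV accuracy, then
smaller subsets, then lexicographic order — a parsimony preference.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import EncodingConfig, encode_set
from .errors import EncodingError, ParseError, ValidationError
from .evaluation import CVResult, cross_validate, roc_auc
from .seqio import LabeledPeptideSet
from .svm_model import KernelSpec, TapBinderClassifier

#: The 32 published position subsets of the truncation study, in their
#: original model numbering (model 10 = {1,2,3,9} is the reference model).
TABLE1_SUBSETS: tuple[tuple[int, ...], ...] = (
    (2, 3),
    (2, 9),
    (3, 9),
    (1, 2, 3),
    (1, 2, 9),
    (1, 3, 9),
    (2, 3, 9),
    (1, 2, 3, 7),
    (1, 2, 3, 8),
    (1, 2, 3, 9),
    (1, 2, 7, 9),
    (1, 2, 8, 9),
    (1, 3, 7, 9),
    (1, 3, 8, 9),
    (2, 3, 7, 9),
    (2, 3, 8, 9),
    (1, 2, 3, 7, 8),
    (1, 2, 3, 8, 9),
    (1, 2, 7, 8, 9),
    (1, 2, 3, 7, 9),
    (1, 3, 7, 8, 9),
    (2, 3, 7, 8, 9),
    (1, 2, 3, 4, 5, 6),
    (1, 2, 3, 7, 8, 9),
    (4, 5, 6, 7, 8, 9),
    (1, 2, 3, 4, 7, 8, 9),
    (1, 2, 3, 5, 7, 8, 9),
    (1, 2, 3, 6, 7, 8, 9),
    (1, 2, 3, 5, 6, 7, 8, 9),
    (1, 2, 3, 4, 6, 7, 8, 9),
    (1, 2, 3, 4, 5, 7, 8, 9),
    (1, 2, 3, 4, 5, 6, 7, 8, 9),
)


def candidate_subsets(
    mode: str = "table1", custom_path: str | Path | None = None
) -> list[tuple[int, ...]]:
    """Enumerate candidate position subsets.

    ``table1``: the 32 published subsets. ``exhaustive-anchored``: all
    subsets of {1..9} of size 2-9 containing at least one N-terminal anchor
    (1-3) and at least one C-terminal anchor (7-9). ``custom``: one
    comma-separated subset per line of ``custom_path``.
    """
    if mode == "table1":
        return list(TABLE1_SUBSETS)
    if mode == "exhaustive-anchored":
        out = []
        for size in range(2, 10):
            for combo in itertools.combinations(range(1, 10), size):
                s = set(combo)
                if s & {1, 2, 3} and s & {7, 8, 9}:
                    out.append(combo)
        return out
    if mode == "custom":
        if custom_path is None:
            raise ValidationError("custom mode requires a subsets file")
        subsets = []
        with open(custom_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    parts = tuple(sorted(int(t) for t in line.split(",")))
                except ValueError as exc:
                    raise ParseError(
                        f"{custom_path}:{lineno}: malformed subset {line!r}"
                    ) from exc
                if not parts:
                    raise ParseError(f"{custom_path}:{lineno}: empty subset")
                subsets.append(parts)
        if not subsets:
            raise ParseError(f"{custom_path}: no subsets found")
        return subsets
    raise ValidationError(f"unknown subset mode {mode!r}")


@dataclass
class ModelCandidate:
    model_no: int
    positions: tuple[int, ...]
    cv_acc: float
    cv_auc: float
    cv: CVResult | None = None
    test_acc: float | None = None
    test_auc: float | None = None
    failed: bool = False
    error: str | None = None


@dataclass
class SelectionReport:
    """Candidates ranked by CV AROC; ``best`` is the selected encoding."""

    candidates: list[ModelCandidate]
    best: ModelCandidate
    seed: int
    k: int

    def to_rows(self) -> list[dict]:
        return [
            {
                "model_no": c.model_no,
                "positions": ",".join(map(str, c.positions)),
                "n_positions": len(c.positions),
                "cv_acc": None if c.failed else round(c.cv_acc, 4),
                "cv_auc": None if c.failed else round(c.cv_auc, 4),
                "test_acc": None if c.test_acc is None else round(c.test_acc, 4),
                "test_auc": None if c.test_auc is None else round(c.test_auc, 4),
                "failed": c.failed,
            }
            for c in self.candidates
        ]

    def write_tsv(self, path: str | Path) -> None:
        rows = self.to_rows()
        cols = ["model_no", "positions", "n_positions", "cv_acc", "cv_auc",
                "test_acc", "test_auc", "failed"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join("" if row[c] is None else str(row[c]) for c in cols) + "\n")

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "k": self.k,
                    "best": {
                        "model_no": self.best.model_no,
                        "positions": list(self.best.positions),
                        "cv_acc": self.best.cv_acc,
                        "cv_auc": self.best.cv_auc,
                        "test_acc": self.best.test_acc,
                        "test_auc": self.best.test_auc,
                    },
                    "candidates": self.to_rows(),
                },
                fh,
                indent=2,
            )


def _rank_key(c: ModelCandidate):
    # descending cv_auc, then descending cv_acc, then parsimony, then lexicographic
    return (-c.cv_auc, -c.cv_acc, len(c.positions), c.positions)


def truncation_analysis(
    pset: LabeledPeptideSet,
    subsets: Sequence[Sequence[int]],
    kernel: KernelSpec | None = None,
    C: float = 1.0,
    k: int = 5,
    seed: int = 0,
    test_set: LabeledPeptideSet | None = None,
    descriptors: Sequence[str] | None = None,
) -> SelectionReport:
    """Cross-validate every candidate subset and select the best encoding.

    All subsets share the fold partition generated from ``seed``, enabling
    paired comparison. A subset whose encoding fails is recorded as failed,
    not fatal. If ``test_set`` is given, the winner is retrained on the full
    training set and evaluated once on the held-out set.
    """
    kernel = kernel or KernelSpec()
    candidates: list[ModelCandidate] = []
    desc_kwargs = {} if descriptors is None else {"descriptors": tuple(descriptors)}
    for i, subset in enumerate(subsets, start=1):
        positions = tuple(sorted(int(p) for p in subset))
        try:
            config = EncodingConfig(positions=positions, **desc_kwargs)
            cv = cross_validate(pset, config, kernel=kernel, C=C, k=k, seed=seed)
        except (EncodingError, ValidationError) as exc:
            candidates.append(
                ModelCandidate(
                    model_no=i, positions=positions, cv_acc=0.0, cv_auc=0.0,
                    failed=True, error=str(exc),
                )
            )
            continue
        candidates.append(
            ModelCandidate(
                model_no=i, positions=positions,
                cv_acc=cv.acc, cv_auc=cv.auc, cv=cv,
            )
        )
    ok = [c for c in candidates if not c.failed]
    if not ok:
        raise ValidationError("every candidate subset failed to encode")
    ranked = sorted(ok, key=_rank_key) + [c for c in candidates if c.failed]
    best = ranked[0]
    if test_set is not None:
        test_set.require_both_classes()
        config = EncodingConfig(positions=best.positions, **desc_kwargs)
        X_tr, y_tr = encode_set(pset, config)
        X_te, y_te = encode_set(test_set, config)
        clf = TapBinderClassifier(
            kernel=kernel.kind, C=C, gamma=kernel.gamma,
            degree=kernel.degree, coef0=kernel.coef0,
        ).fit(X_tr, y_tr)
        scores = clf.decision_function(X_te)
        pred = np.where(scores > 0, 1, -1)
        best.test_acc = float(np.mean(pred == y_te))
        best.test_auc = roc_auc(scores, y_te).auc
    return SelectionReport(candidates=ranked, best=best, seed=seed, k=k)
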