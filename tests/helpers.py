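"""Independent oracles and builders shared across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from fatiguekin.features import CLASSES, FEATURE_IDS


def brute_force_macro_ovr_auc(labels, probabilities) -> float:
    """All-pairs rank oracle for macro one-vs-rest ROC AUC.

    For each class with at least one positive and one negative, count over
    every (positive, negative) pair: 1 if the positive's score is higher,
    0.5 on ties. Macro = unweighted mean. Kept deliberately independent of
    the package's rank-statistic implementation.
    """
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities)
    aucs = []
    for j, c in enumerate(CLASSES):
        pos = np.flatnonzero(labels == c)
        neg = np.flatnonzero(labels != c)
        if len(pos) == 0 or len(neg) == 0:
            continue
        credit = 0.0
        for p in pos:
            for n in neg:
                sp, sn = probabilities[p, j], probabilities[n, j]
                credit += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        aucs.append(credit / (len(pos) * len(neg)))
    return float(np.mean(aucs))


def make_feature_table(
    labels_per_subject: dict[str, list[str]],
    rng: np.random.Generator,
    class_shift: float = 0.0,
) -> pd.DataFrame:
    """A synthetic classifier input table with given labels per subject.

    Features are standard normal noise; ``class_shift`` adds a per-class
    mean offset on the first two features to make classes separable.
    """
    rows = []
    for sid, labels in labels_per_subject.items():
        for k, lab in enumerate(labels):
            feats = rng.normal(size=len(FEATURE_IDS))
            shift = class_shift * CLASSES.index(lab)
            feats[0] += shift
            feats[1] -= shift
            row = {"subject_id": sid, "window_index": k,
                   "t_start": 10.0 * k, "t_end": 10.0 * k + 8.0}
            row.update(dict(zip(FEATURE_IDS, feats)))
            row["cr10"] = {"Low": 2, "Medium": 5, "High": 8}[lab]
            row["label"] = lab
            rows.append(row)
    return pd.DataFrame(rows)
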