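"""Supervised detection of expressed (active) transcripts.

Training labels come from the Pol II RPKM extremes (top and bottom deciles),
a linear maximum-margin classifier is trained per time point on chromatin
features around the TSS/TES and gene body, and a transcript counts as active
when classified active at one or more time points. Transcripts too short for
body features are rescued by an RPKM rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.model_selection import cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC


def rpkm(counts, lengths_bp, library_size) -> np.ndarray:
    """Reads per kilobase per million mapped reads."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths_bp, dtype=float)
    return counts * 1e9 / (lengths * float(library_size))


def make_labels(polii_rpkm: pd.Series) -> tuple[list, list]:
    """Top-decile transcripts become the active training set, bottom decile
    the inactive set; boundary ties are resolved by transcript id order."""
    if len(polii_rpkm) < 20:
        raise ValueError("need at least 20 transcripts for decile labels")
    if polii_rpkm.nunique() == 1:
        raise ValueError("all-equal RPKM: deciles undefined")
    k = len(polii_rpkm) // 10
    ordered = polii_rpkm.sort_index().sort_values(kind="stable")
    inactive = list(ordered.index[:k])
    active = list(ordered.index[-k:])
    return active, inactive


def classify_transcripts(features: dict[float, pd.DataFrame], active_ids, inactive_ids,
                         min_cv_accuracy: float = 0.95, seed: int = 0):
    """Train a per-time-point linear margin classifier on the label extremes
    and apply it to all transcripts.

    ``features`` maps time point -> (transcripts x feature) matrix; the same
    rows must exist at every time point. Returns (flags DataFrame with one
    boolean column per time, final active id set, cross-validated accuracies).
    """
    times = sorted(features)
    if not times:
        raise ValueError("no feature matrices supplied")
    index = features[times[0]].index
    train_ids = list(active_ids) + list(inactive_ids)
    if not active_ids or not inactive_ids:
        raise ValueError("both label sets must be nonempty")
    y = np.array([1] * len(active_ids) + [0] * len(inactive_ids))
    flags = pd.DataFrame(index=index)
    accuracies = {}
    for t in times:
        X = features[t]
        if X.isna().any().any():
            raise ValueError(f"missing feature blocks at time {t}")
        clf = make_pipeline(StandardScaler(),
                            LinearSVC(C=1.0, random_state=seed, max_iter=20000))
        Xtr = X.loc[train_ids].to_numpy()
        accuracies[t] = float(np.mean(cross_val_score(clf, Xtr, y, cv=5)))
        clf.fit(Xtr, y)
        flags[t] = clf.predict(X.to_numpy()).astype(bool)
    active_set = set(flags.index[flags.any(axis=1)])
    return flags, active_set, accuracies


def short_transcript_rule(short_ids, polii_rpkm: pd.Series, active_set: set) -> set:
    """Add short transcripts whose RPKM strictly exceeds the lower quartile of
    the current active set (linear-interpolation quartile)."""
    if not active_set:
        raise ValueError("active set must be nonempty")
    q25 = float(np.percentile(polii_rpkm.loc[sorted(active_set)], 25))
    amended = set(active_set)
    for tid in short_ids:
        if float(polii_rpkm.loc[tid]) > q25:
            amended.add(tid)
    return amended
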