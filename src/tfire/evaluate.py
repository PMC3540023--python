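"""Prediction-quality metrics and benchmark-style summaries.

Sensitivity is TP/(TP+FN) over annotated sites; specificity is TP/(TP+FP)
where FP counts predicted windows matching no site.  ROC curves treat lower
energy as more positive, with negatives taken from the retained candidate
windows that overlap no annotated site.  Also here: the paired t-test used to
compare PWM dissimilarity columns, the threading-decoy discrimination test
(success ratio and Z-score of the native sequence against random sequences on
the fixed backbone), native base-pair recovery, and the benchmark summary
table with Average / Standard Deviation rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve


class ConfusionCounts(NamedTuple):
    tp: int
    fn: int
    fp: int
    tn: int | None = None


@dataclass
class RocCurve:
    points: list[tuple[float, float]]  # (FPR, TPR)
    auc: float


def sensitivity(counts: ConfusionCounts) -> float:
    """TP/(TP+FN); 0 with a warning when there are no annotated sites."""
    denom = counts.tp + counts.fn
    if denom == 0:
        warnings.warn("sensitivity undefined (tp + fn = 0); returning 0", stacklevel=2)
        return 0.0
    return counts.tp / denom


def specificity(counts: ConfusionCounts) -> float:
    """TP/(TP+FP); 0 with a warning when nothing was predicted."""
    denom = counts.tp + counts.fp
    if denom == 0:
        warnings.warn("specificity undefined (tp + fp = 0); returning 0", stacklevel=2)
        return 0.0
    return counts.tp / denom


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC over window energies (lower energy = called positive earlier).

    Equal scores collapse to one threshold; the AUC is the trapezoidal area,
    identical to the normalized Mann-Whitney U count.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), -scores)
    return RocCurve(list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr)))


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Classic paired t on the differences, df = n - 1, two-tailed p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs two equal-length samples of size >= 2")
    if np.allclose(a, b):
        if np.all(a == b):
            return 0.0, 1.0
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        raise ValueError("paired t-test degenerate: constant differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# structure-level tests of an energy function


def threading_decoy_test(potential, structure, n_decoys: int, seed: int
                         ) -> tuple[float, float]:
    """Discriminate the native binding-site sequence from random ones.

    Random full-length sequences are threaded onto the fixed backbone via
    base-pair substitution and scored; returns the fraction of decoys with
    energy above the native sequence and the Z-score
    (E_native - mean) / sd of the native energy in the decoy distribution
    (the lower the better).
    """
    from .pem import BASE_INDEX, build_pem
    from .synthetic import make_threading_decoys

    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    pem = build_pem(potential, structure)
    native = np.array(pem.native)
    rows = np.arange(pem.L)
    e_native = float(pem.energies[rows, native].sum())
    decoys = make_threading_decoys(pem.L, n_decoys, seed)
    energies = np.array([pem.energies[rows, [BASE_INDEX[b] for b in d]].sum()
                         for d in decoys])
    sd = float(np.std(energies, ddof=1)) if n_decoys > 1 else 0.0
    if sd == 0:
        raise ValueError("decoy energies are constant; Z-score undefined")
    ratio = float(np.mean(energies > e_native))
    z = (e_native - float(energies.mean())) / sd
    return ratio, z


def basepair_recovery(potential, structure) -> float:
    """Fraction of binding-site positions whose native pair is the strict minimum."""
    from .pem import build_pem

    pem = build_pem(potential, structure)
    recovered = 0
    for row, native in enumerate(pem.native):
        e = pem.energies[row]
        if np.all(np.delete(e, native) > e[native]):
            recovered += 1
    return recovered / pem.L if pem.L else 0.0


def rank_decoys(potential, structures) -> list[tuple[int, float]]:
    """Rank arbitrary decoy complexes by total interaction energy (ascending)."""
    from .potential import interaction_energy

    energies = [(i, interaction_energy(potential, s)) for i, s in enumerate(structures)]
    return sorted(energies, key=lambda t: t[1])


# ---------------------------------------------------------------------------
# summary table


SUMMARY_COLUMNS = ["tf_id", "tp", "fn", "fp", "se", "sp", "se_plus_sp", "auc",
                   "n_top_sites", "n_sites", "n_top_orfs", "n_orfs"]


def summarize(per_tf: list[dict]) -> pd.DataFrame:
    """Benchmark-style table with per-TF rows plus Average and SD rows.

    Each input row carries tf_id, a ConfusionCounts (or tp/fn/fp), an AUC and
    the rank bookkeeping counts.  Averages are unweighted column means and SD
    the sample (n-1) standard deviation, both computed at full precision
    before the 2-decimal half-up rounding used throughout the report.
    """
    rows = []
    for entry in per_tf:
        entry = dict(entry)
        counts = entry.pop("counts", None)
        if counts is not None:
            entry.setdefault("tp", counts.tp)
            entry.setdefault("fn", counts.fn)
            entry.setdefault("fp", counts.fp)
        c = ConfusionCounts(tp=entry["tp"], fn=entry["fn"], fp=entry["fp"])
        se = entry.get("se", sensitivity(c))
        sp = entry.get("sp", specificity(c))
        rows.append({
            "tf_id": entry["tf_id"], "tp": entry["tp"], "fn": entry["fn"],
            "fp": entry["fp"], "se": se, "sp": sp, "se_plus_sp": se + sp,
            "auc": entry.get("auc", math.nan),
            "n_top_sites": entry.get("n_top_sites", 0),
            "n_sites": entry.get("n_sites", 0),
            "n_top_orfs": entry.get("n_top_orfs", 0),
            "n_orfs": entry.get("n_orfs", 0),
        })
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    numeric = table.columns.drop("tf_id")
    out = table.copy()
    out[numeric] = out[numeric].apply(_round_half_up)
    mean = table[numeric].mean()
    avg_row = {"tf_id": "Average", **{c: _round_half_up(float(mean[c])) for c in numeric}}
    if len(table) > 1:
        sd = table[numeric].std(ddof=1)
        sd_row = {"tf_id": "Standard Deviation",
                  **{c: _round_half_up(float(sd[c])) for c in numeric}}
    else:
        sd_row = {"tf_id": "Standard Deviation", **{c: math.nan for c in numeric}}
    return pd.concat([out, pd.DataFrame([avg_row, sd_row])], ignore_index=True)


def _round_half_up(x, decimals: int = 2):
    scaled = np.asarray(x, dtype=float) * 10 ** decimals
    rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) / 10 ** decimals
    return rounded if np.ndim(x) else float(rounded)
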