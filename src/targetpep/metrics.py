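"""Evaluation metrics: MCC, F1, cleavage-site accuracy and segment overlap.

MCC and F1 are computed from per-class confusion counts over protein-level
multi-label calls.  Cleavage-site accuracy for the terminus-anchored
classes is the fraction of *predicted* proteins of the class whose free-end
position is exactly right (the denominator is the prediction count, so a
never-predicted class is not-applicable rather than 0).  NLS/NES position
quality uses the segment-overlap measure

    SOV = sum_i min(OV(i), alpha_i * union(i)) / sum_i |S_obs,i|,
    alpha_i = 1 - | |S_obs,i| - |S_pred,i| | / union(i),

where each observed segment i is paired with the single predicted segment
of maximal overlap (ties to the earlier predicted segment; no overlap
contributes 0).  The classical SOV'99 all-pairs variant is available as
``mode="sov99"``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import INTERNAL_CLASSES, SIGNAL_CLASSES
from .infer import Segment, cleavage_site
from .seqio import SignalAnnotation

__all__ = [
    "ConfusionCounts",
    "mcc",
    "f1",
    "cleavage_accuracy",
    "sov",
    "sov_parts",
    "evaluate_dataset",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    if counts.total == 0:
        raise ValueError("MCC is undefined for all-zero counts")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def f1(counts: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 by convention when empty."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp == 0 or tp + fn == 0 or tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def cleavage_accuracy(
    predictions: Mapping[str, int | None],
    truths: Mapping[str, int | None],
) -> float | None:
    """Exact-match fraction among proteins *predicted* as the class.

    Returns ``None`` (not applicable) when nothing was predicted.
    """
    predicted = {pid: site for pid, site in predictions.items()
                 if site is not None}
    if not predicted:
        return None
    correct = sum(
        1 for pid, site in predicted.items() if truths.get(pid) == site
    )
    return correct / len(predicted)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _union(a: tuple[int, int], b: tuple[int, int]) -> int:
    la = a[1] - a[0] + 1
    lb = b[1] - b[0] + 1
    return la + lb - _overlap(a, b)


def _check_segment_set(spans: Sequence[tuple[int, int]], role: str) -> None:
    spans = sorted(spans)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"{role} segments overlap: {(s1,e1)} vs {(s2,e2)}")
    for s, e in spans:
        if s > e:
            raise ValueError(f"invalid {role} span {(s, e)}")


def sov(
    observed: Sequence[tuple[int, int]],
    predicted: Sequence[tuple[int, int]],
    mode: str = "paper",
) -> float:
    """Segment overlap score between two span sets of one class.

    Spans are 1-based inclusive (start, end) pairs.  ``mode="paper"`` pairs
    each observed segment with its maximal-overlap predicted segment;
    ``mode="sov99"`` is the classical all-overlapping-pairs definition.
    Raises on an empty observed set (not-applicable is the caller's call).
    """
    observed = [tuple(s) for s in observed]
    predicted = [tuple(s) for s in predicted]
    if not observed:
        raise ValueError("SOV is undefined for an empty observed set")
    _check_segment_set(observed, "observed")
    _check_segment_set(predicted, "predicted")
    predicted = sorted(predicted)

    numer, denom = sov_parts(observed, predicted, mode)
    return numer / denom


def sov_parts(
    observed: Sequence[tuple[int, int]],
    predicted: Sequence[tuple[int, int]],
    mode: str = "paper",
) -> tuple[float, float]:
    """Numerator and denominator of the SOV score (for corpus pooling)."""
    observed = sorted(tuple(s) for s in observed)
    predicted = sorted(tuple(s) for s in predicted)
    if mode == "paper":
        numer = 0.0
        denom = 0
        for obs in observed:
            obs_len = obs[1] - obs[0] + 1
            denom += obs_len
            best = None
            best_ov = 0
            for pred in predicted:  # earlier predicted segment wins ties
                ov = _overlap(obs, pred)
                if ov > best_ov:
                    best, best_ov = pred, ov
            if best is None:
                continue
            union = _union(obs, best)
            pred_len = best[1] - best[0] + 1
            alpha = 1.0 - abs(obs_len - pred_len) / union
            numer += min(best_ov, alpha * union)
        return numer, denom
    if mode == "sov99":
        numer = 0.0
        denom = 0
        for obs in observed:
            obs_len = obs[1] - obs[0] + 1
            overlapping = [p for p in predicted if _overlap(obs, p) > 0]
            if not overlapping:
                denom += obs_len
                continue
            denom += len(overlapping) * obs_len
            for pred in overlapping:
                pred_len = pred[1] - pred[0] + 1
                minov = _overlap(obs, pred)
                maxov = _union(obs, pred)
                delta = min(
                    maxov - minov, minov, obs_len // 2, pred_len // 2
                )
                numer += (minov + delta) / maxov * obs_len
        return numer, denom
    raise ValueError(f"unknown SOV mode {mode!r}")


def evaluate_dataset(
    predictions: Mapping[str, Sequence[Segment]],
    truths: Mapping[str, Sequence[SignalAnnotation]],
    lengths: Mapping[str, int],
    sov_mode: str = "paper",
    sov_pooling: str = "protein",
) -> pd.DataFrame:
    """Per-class metrics table over an aligned prediction/truth set.

    ``truths`` maps every protein id to its (possibly empty) annotation
    list; ``predictions`` must cover the same proteins.  The table carries
    protein-level MCC and F1 for all 8 classes, cleavage accuracy for the
    terminus-anchored classes, SOV for NLS/NES (``sov_pooling="protein"``
    averages per-protein scores unweighted; ``"corpus"`` pools segment
    numerators/denominators across proteins), and unweighted /
    truth-count-weighted averages across classes.
    """
    if sov_pooling not in ("protein", "corpus"):
        raise ValueError(f"unknown sov_pooling {sov_pooling!r}")
    missing = set(truths) - set(predictions)
    if missing:
        raise ValueError(
            f"predictions missing for {len(missing)} proteins, "
            f"e.g. {sorted(missing)[:3]}"
        )
    proteins = sorted(truths)

    rows = {}
    for cls in SIGNAL_CLASSES:
        true_bits = {
            pid: any(a.signal_class == cls for a in truths[pid])
            for pid in proteins
        }
        pred_bits = {
            pid: any(s.signal_class == cls for s in predictions[pid])
            for pid in proteins
        }
        tp = sum(true_bits[p] and pred_bits[p] for p in proteins)
        fp = sum(not true_bits[p] and pred_bits[p] for p in proteins)
        fn = sum(true_bits[p] and not pred_bits[p] for p in proteins)
        tn = len(proteins) - tp - fp - fn
        counts = ConfusionCounts(tp, fp, tn, fn)
        n_true = sum(true_bits.values())
        row = {
            "n_proteins": n_true,
            "mcc": mcc(counts) if counts.total else np.nan,
            "f1": f1(counts),
            "cleavage_accuracy": np.nan,
            "sov": np.nan,
        }
        if cls in INTERNAL_CLASSES:
            scores = []
            pooled_num = pooled_den = 0.0
            for pid in proteins:
                obs = [(a.start, a.end) for a in truths[pid]
                       if a.signal_class == cls]
                if not obs:
                    continue
                pred = [(s.start, s.end) for s in predictions[pid]
                        if s.signal_class == cls]
                scores.append(sov(obs, pred, mode=sov_mode))
                num, den = sov_parts(obs, pred, mode=sov_mode)
                pooled_num += num
                pooled_den += den
            if not scores:
                row["sov"] = np.nan
            elif sov_pooling == "protein":
                row["sov"] = float(np.mean(scores))
            else:
                row["sov"] = pooled_num / pooled_den
        else:
            pred_sites = {
                pid: cleavage_site(list(predictions[pid]), cls, lengths[pid])
                for pid in proteins
            }
            true_sites = {}
            for pid in proteins:
                true_segs = [
                    Segment(pid, a.signal_class, a.start, a.end)
                    for a in truths[pid]
                ]
                true_sites[pid] = cleavage_site(true_segs, cls, lengths[pid])
            acc = cleavage_accuracy(pred_sites, true_sites)
            row["cleavage_accuracy"] = np.nan if acc is None else acc
        rows[cls] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    metric_cols = ["mcc", "f1", "cleavage_accuracy", "sov"]
    avg = table[metric_cols].mean(skipna=True)
    weights = table["n_proteins"].to_numpy(dtype=float)
    wavg = {}
    for col in metric_cols:
        vals = table[col].to_numpy(dtype=float)
        ok = ~np.isnan(vals) & (weights > 0)
        wavg[col] = (
            float(np.average(vals[ok], weights=weights[ok])) if ok.any()
            else np.nan
        )
    table.loc["Average"] = {"n_proteins": int(table["n_proteins"].sum()),
                            **avg.to_dict()}
    table.loc["Weighted average"] = {
        "n_proteins": int(table["n_proteins"].sum()), **wavg
    }
    return table
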