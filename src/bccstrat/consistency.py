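"""Dual-outcome consistency: etiology rerun, overlaps, and direction labels.

Clusters that are stable for recanalization success are re-analyzed with
stroke etiology as the outcome (cardioembolism vs large-artery
atherosclerosis by default; undetermined-etiology patients are excluded in
that mode).  The intersection of the two stable sets per sex, the overlap
between sexes, and the outcome class in which each cluster representative's
median is highest give the biological-consistency map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .validation import StabilityResult, ValidationError, repeated_cv

logger = logging.getLogger(__name__)


class ConsistencyError(ValueError):
    pass


@dataclass
class ConsistencyMap:
    """Per-sex stable sets for both outcomes, their overlaps, and directions."""

    recan_stable: dict[str, set[str]]  # sex -> clusters
    etiology_stable: dict[str, set[str]]
    both_stable: dict[str, set[str]]  # intersection, per sex
    shared_across_sexes: dict[str, set[str]]  # per stage: recan / both
    sex_specific: dict[str, dict[str, set[str]]]  # stage -> sex -> clusters
    direction: dict[str, dict[str, dict[str, str]]] = field(default_factory=dict)
    # direction[outcome][sex][cluster] = class label with highest median (or "none")


def _restrict_partition(partition: dict[str, int], clusters: set[str]) -> dict[str, int]:
    wanted = {int(c.split("_")[1]) for c in clusters}
    return {v: c for v, c in partition.items() if c in wanted}


def etiology_stability(
    X: pd.DataFrame,
    etiology,
    sex,
    partition: dict[str, int],
    candidate_clusters: dict[str, set[str]],
    mode: str = "binary",
    **cv_kwargs,
) -> dict[str, StabilityResult]:
    """Stability selection with stroke etiology as the outcome, per sex.

    Candidate variables are restricted to the recanalization-stable clusters
    of each sex.  ``mode="binary"`` contrasts CE vs LAA (UND excluded);
    ``mode="three_class"`` keeps all three etiology classes.
    """
    if mode not in ("binary", "three_class"):
        raise ConsistencyError(f"unknown etiology mode {mode!r}")
    etiology = np.asarray(etiology)
    sex = np.asarray(sex)
    K = cv_kwargs.get("K", 5)
    out: dict[str, StabilityResult] = {}
    for s in ("F", "M"):
        cand = candidate_clusters.get(s, set())
        if not cand:
            logger.info("sex %s: no recanalization-stable clusters; skipping etiology run", s)
            continue
        mask = sex == s
        if mode == "binary":
            mask = mask & np.isin(etiology, ["CE", "LAA"])
        ys = etiology[mask]
        classes, counts = np.unique(ys, return_counts=True)
        if counts.min() < K:
            raise ConsistencyError(
                f"sex {s}: etiology class with fewer than K={K} members "
                f"({dict(zip(classes, counts))})"
            )
        sub_partition = _restrict_partition(partition, cand)
        Xs = X.loc[mask, list(sub_partition)].reset_index(drop=True)
        out[s] = repeated_cv(Xs, ys, partition=sub_partition, **cv_kwargs)
    return out


def direction_assignment(
    reps: pd.DataFrame, labels, stable_clusters: set[str]
) -> dict[str, str]:
    """For each stable cluster, the outcome class with the highest median.

    Exact ties yield direction ``"none"`` (logged).  Invariant to monotone
    rescaling of a representative.
    """
    if not stable_clusters:
        raise ConsistencyError("stable set is empty")
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))
    out: dict[str, str] = {}
    for c in sorted(stable_clusters):
        medians = {cls: float(np.median(reps.loc[labels == cls, c])) for cls in classes}
        top = max(medians.values())
        winners = [cls for cls, m in medians.items() if m == top]
        if len(winners) > 1:
            logger.info("cluster %s: exact median tie between %s", c, winners)
            out[c] = "none"
        else:
            out[c] = winners[0]
    return out


def overlap_summary(stable_F: set[str], stable_M: set[str]) -> dict[str, int]:
    """Shared / female-specific / male-specific cluster counts."""
    shared = stable_F & stable_M
    return {
        "shared": len(shared),
        "female_specific": len(stable_F - stable_M),
        "male_specific": len(stable_M - stable_F),
    }


def _stable_sets(results) -> dict[str, set[str]]:
    return {
        s: set(r.stable_set) if hasattr(r, "stable_set") else set(r)
        for s, r in results.items()
    }


def build_consistency_map(
    recan_results,
    etiology_results,
    reps_by_sex: dict[str, pd.DataFrame] | None = None,
    recan_labels: dict[str, np.ndarray] | None = None,
    etiology_labels: dict[str, np.ndarray] | None = None,
) -> ConsistencyMap:
    """Assemble the full consistency map from per-sex stability results.

    ``recan_results`` / ``etiology_results`` map sex to either a
    StabilityResult or a plain set of stable cluster names.
    """
    recan_stable = _stable_sets(recan_results)
    et_stable = _stable_sets(etiology_results)
    both = {
        s: recan_stable.get(s, set()) & et_stable.get(s, set())
        for s in recan_stable
    }
    shared = {
        "recan": recan_stable.get("F", set()) & recan_stable.get("M", set()),
        "both": both.get("F", set()) & both.get("M", set()),
    }
    sex_specific = {
        "recan": {
            "F": recan_stable.get("F", set()) - recan_stable.get("M", set()),
            "M": recan_stable.get("M", set()) - recan_stable.get("F", set()),
        },
        "both": {
            "F": both.get("F", set()) - both.get("M", set()),
            "M": both.get("M", set()) - both.get("F", set()),
        },
    }
    cmap = ConsistencyMap(
        recan_stable=recan_stable,
        etiology_stable=et_stable,
        both_stable=both,
        shared_across_sexes=shared,
        sex_specific=sex_specific,
    )
    if reps_by_sex is not None:
        cmap.direction = {"recanalization": {}, "etiology": {}}
        for s, reps in reps_by_sex.items():
            if recan_labels is not None and recan_stable.get(s):
                cmap.direction["recanalization"][s] = direction_assignment(
                    reps, recan_labels[s], recan_stable[s]
                )
            if etiology_labels is not None and et_stable.get(s):
                mask = np.isin(etiology_labels[s], ["CE", "LAA"])
                cmap.direction["etiology"][s] = direction_assignment(
                    reps.loc[mask], np.asarray(etiology_labels[s])[mask], et_stable[s]
                )
    return cmap


def consistency_report(cmap: ConsistencyMap) -> str:
    """Human-readable markdown summary of the consistency map."""
    lines = ["# Dual-outcome consistency", ""]
    for s in ("F", "M"):
        label = "Women" if s == "F" else "Men"
        rs = sorted(cmap.recan_stable.get(s, set()))
        es = sorted(cmap.etiology_stable.get(s, set()))
        bs = sorted(cmap.both_stable.get(s, set()))
        lines += [
            f"## {label}",
            f"- recanalization-stable clusters ({len(rs)}): {', '.join(rs) or '-'}",
            f"- etiology-stable clusters ({len(es)}): {', '.join(es) or '-'}",
            f"- stable for both outcomes ({len(bs)}): {', '.join(bs) or '-'}",
            "",
        ]
    ov = overlap_summary(cmap.recan_stable.get("F", set()), cmap.recan_stable.get("M", set()))
    ov2 = overlap_summary(cmap.both_stable.get("F", set()), cmap.both_stable.get("M", set()))
    lines += [
        "## Overlap across sexes",
        f"- recanalization stage: {ov['shared']} shared, "
        f"{ov['female_specific']} female-specific, {ov['male_specific']} male-specific",
        f"- both-outcome stage: {ov2['shared']} shared, "
        f"{ov2['female_specific']} female-specific, {ov2['male_specific']} male-specific",
        "",
    ]
    for outcome, per_sex in cmap.direction.items():
        lines.append(f"## Direction of effect ({outcome})")
        for s, d in per_sex.items():
            for c, cls in sorted(d.items()):
                lines.append(f"- {s} {c}: median highest in {cls}")
        lines.append("")
    return "\n".join(lines)
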