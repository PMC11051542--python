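"""Rater-consensus ground truth and concordance statistics.

Ground truth for dipole labeling is established by a panel of expert raters
(three neuroradiologists in the clinical setting). Each rater assigns a label
— or a *set* of acceptable labels when a dipole sits in a sulcus and either
adjacent gyrus would be correct. A label becomes the consensus when at least
``threshold_count`` raters endorse it (2 of 3 by default, i.e. a floor
agreement of 66 %).

Concordance then compares the pipeline's per-dipole labels against that
consensus. Percentages are always reported alongside their integer numerator
and denominator so rounding is auditable, and the two denominators are
explicit: concordant % is computed over *labeled* dipoles, unlabeled % over
all considered dipoles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

from .atlas import LabelResult

__all__ = [
    "NO_CONSENSUS",
    "ConcordanceReport",
    "DiscrepancyReport",
    "consensus",
    "consensus_floor_pct",
    "concordance",
    "method_discrepancy",
    "read_rater_file",
    "consensus_from_raters",
]

LabelOrSet = Union[str, frozenset, set]

NO_CONSENSUS = "<no consensus>"


def _as_set(value: LabelOrSet) -> frozenset:
    if isinstance(value, str):
        return frozenset({value})
    return frozenset(value)


def consensus(
    labels_per_rater: Sequence[LabelOrSet], threshold_count: int = 2
) -> str:
    """Consensus label across raters, or :data:`NO_CONSENSUS`.

    A rater endorses label ``L`` if ``L`` is their label or a member of their
    acceptable set. The label endorsed by at least ``threshold_count`` raters
    wins; if several distinct labels tie for the highest qualifying
    endorsement count, there is no consensus. Invariant under rater order.
    """
    if not labels_per_rater:
        raise ValueError("consensus requires at least one rater")
    if len(labels_per_rater) < threshold_count:
        raise ValueError(
            f"need >= {threshold_count} raters, got {len(labels_per_rater)}"
        )
    rater_sets = [_as_set(v) for v in labels_per_rater]
    candidates = set().union(*rater_sets)
    counts = {
        label: sum(label in s for s in rater_sets) for label in candidates
    }
    qualifying = {l: c for l, c in counts.items() if c >= threshold_count}
    if not qualifying:
        return NO_CONSENSUS
    top = max(qualifying.values())
    winners = [l for l, c in qualifying.items() if c == top]
    if len(winners) > 1:
        return NO_CONSENSUS
    return winners[0]


def consensus_floor_pct(threshold_count: int = 2, n_raters: int = 3) -> int:
    """Minimum agreement percentage implied by a k-of-n consensus rule.

    2 of 3 raters -> floor(100 * 2/3) = 66 %.
    """
    if not 1 <= threshold_count <= n_raters:
        raise ValueError("threshold_count must be in [1, n_raters]")
    return math.floor(100 * threshold_count / n_raters)


@dataclass
class ConcordanceReport:
    """Agreement between pipeline labels and a reference labeling.

    ``concordant_pct`` uses the labeled-dipole denominator; ``unlabeled_pct``
    uses all considered dipoles. Raw counts are always carried so the
    percentages can be audited (and re-rounded) downstream.
    """

    n_considered: int
    n_labeled: int
    n_concordant: int
    n_unlabeled: int
    n_excluded: int = 0
    per_dipole: dict[str, str] = field(default_factory=dict)

    @property
    def concordant_pct(self) -> float:
        if self.n_labeled == 0:
            return 0.0
        return 100.0 * self.n_concordant / self.n_labeled

    @property
    def unlabeled_pct(self) -> float:
        if self.n_considered == 0:
            return 0.0
        return 100.0 * self.n_unlabeled / self.n_considered

    def as_dict(self) -> dict:
        return {
            "n_considered": self.n_considered,
            "n_labeled": self.n_labeled,
            "n_concordant": self.n_concordant,
            "n_unlabeled": self.n_unlabeled,
            "n_excluded": self.n_excluded,
            "concordant_pct": self.concordant_pct,
            "concordant_fraction": f"{self.n_concordant}/{self.n_labeled}",
            "unlabeled_pct": self.unlabeled_pct,
            "unlabeled_fraction": f"{self.n_unlabeled}/{self.n_considered}",
        }


def _pipeline_label(value) -> tuple[bool, str]:
    """Normalize a pipeline-side entry to (is_labeled, label)."""
    if isinstance(value, LabelResult):
        return value.status == "labeled", value.label
    if value is None or value == "":
        return False, ""
    return True, str(value)


def concordance(
    pipeline: Mapping[str, object],
    truth: Mapping[str, LabelOrSet],
    excluded_ids: Sequence[str] = (),
) -> ConcordanceReport:
    """Compare pipeline labels with consensus truth, dipole by dipole.

    ``pipeline`` maps dipole id to a :class:`~meglabel.atlas.LabelResult` (or
    a bare label string; empty/None means unlabeled); ``truth`` maps the same
    ids to the consensus label or acceptable-label set. A labeled dipole is
    concordant iff its label is in the truth set (exact string match). The two
    id universes must coincide after removing ``excluded_ids``.
    """
    excluded = set(excluded_ids)
    pipe_ids = set(pipeline) - excluded
    truth_ids = set(truth) - excluded
    if pipe_ids != truth_ids:
        orphans_p = sorted(pipe_ids - truth_ids)
        orphans_t = sorted(truth_ids - pipe_ids)
        raise ValueError(
            "dipole id mismatch between pipeline and truth; "
            f"only in pipeline: {orphans_p}; only in truth: {orphans_t}"
        )
    n_labeled = n_concordant = n_unlabeled = 0
    per_dipole: dict[str, str] = {}
    for did in sorted(pipe_ids):
        labeled, label = _pipeline_label(pipeline[did])
        if not labeled:
            n_unlabeled += 1
            per_dipole[did] = "unlabeled"
            continue
        n_labeled += 1
        if label in _as_set(truth[did]):
            n_concordant += 1
            per_dipole[did] = "concordant"
        else:
            per_dipole[did] = "discordant"
    return ConcordanceReport(
        n_considered=len(pipe_ids),
        n_labeled=n_labeled,
        n_concordant=n_concordant,
        n_unlabeled=n_unlabeled,
        n_excluded=len(excluded),
        per_dipole=per_dipole,
    )


@dataclass
class DiscrepancyReport:
    """Per-dipole agreement between two pipeline runs (e.g. two normalizations).

    Categories: ``same_label``, ``different_label``, ``only_one_labeled``,
    ``both_unlabeled``. The summary percentage counts labeling discrepancies
    (``different_label`` + ``only_one_labeled``) over all compared dipoles.
    """

    categories: dict[str, str]
    counts: dict[str, int]

    @property
    def n(self) -> int:
        return len(self.categories)

    @property
    def n_discrepant(self) -> int:
        return self.counts["different_label"] + self.counts["only_one_labeled"]

    @property
    def discrepancy_pct(self) -> float:
        return 100.0 * self.n_discrepant / self.n if self.n else 0.0


def method_discrepancy(
    run_a: Mapping[str, object], run_b: Mapping[str, object]
) -> DiscrepancyReport:
    """Categorize per-dipole labeling differences between two runs."""
    if set(run_a) != set(run_b):
        orphans_a = sorted(set(run_a) - set(run_b))
        orphans_b = sorted(set(run_b) - set(run_a))
        raise ValueError(
            "dipole id mismatch between runs; "
            f"only in A: {orphans_a}; only in B: {orphans_b}"
        )
    categories: dict[str, str] = {}
    counts = {
        "same_label": 0,
        "different_label": 0,
        "only_one_labeled": 0,
        "both_unlabeled": 0,
    }
    for did in sorted(run_a):
        la, sa = _pipeline_label(run_a[did])[1], _pipeline_label(run_a[did])[0]
        lb, sb = _pipeline_label(run_b[did])[1], _pipeline_label(run_b[did])[0]
        if sa and sb:
            cat = "same_label" if la == lb else "different_label"
        elif sa or sb:
            cat = "only_one_labeled"
        else:
            cat = "both_unlabeled"
        categories[did] = cat
        counts[cat] += 1
    return DiscrepancyReport(categories=categories, counts=counts)


# ---------------------------------------------------------------------------
# truth files
# ---------------------------------------------------------------------------


def read_rater_file(path) -> dict[str, list[frozenset]]:
    """Read a delimited rater file: ``id<TAB>rater1<TAB>rater2<TAB>...``.

    Each rater cell is a ``|``-separated set of acceptable labels. ``#``
    comments and blank lines are skipped; every dipole must have at least one
    rater and all rows the same rater count.
    """
    path = Path(path)
    out: dict[str, list[frozenset]] = {}
    n_raters = None
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected id and >= 1 rater columns")
        did, cells = parts[0], parts[1:]
        if did in out:
            raise ValueError(f"{path}:{lineno}: duplicate dipole id {did!r}")
        if n_raters is None:
            n_raters = len(cells)
        elif len(cells) != n_raters:
            raise ValueError(
                f"{path}:{lineno}: expected {n_raters} rater columns, got {len(cells)}"
            )
        out[did] = [
            frozenset(x for x in cell.split("|") if x) for cell in cells
        ]
        if any(not s for s in out[did]):
            raise ValueError(f"{path}:{lineno}: empty rater label for {did!r}")
    if not out:
        raise ValueError(f"{path}: no rater rows")
    return out


def consensus_from_raters(
    raters: Mapping[str, Sequence[LabelOrSet]], threshold_count: int = 2
) -> tuple[dict[str, str], list[str]]:
    """Apply the consensus rule per dipole.

    Returns the consensus truth mapping plus the list of dipole ids on which
    the raters failed to reach consensus (to be excluded from concordance).
    """
    truth: dict[str, str] = {}
    no_consensus: list[str] = []
    for did, labels in raters.items():
        result = consensus(labels, threshold_count=threshold_count)
        if result == NO_CONSENSUS:
            no_consensus.append(did)
        else:
            truth[did] = result
    return truth, no_consensus
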