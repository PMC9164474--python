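"""Hierarchical motif/time-course clustering of regulated phosphosites.

Sites are first partitioned by sequence context, in precedence order:

* Group I   — proline at +1 (proline-directed kinase targets, MAPK/CDK),
* Group II  — a basic residue (R/K/H, class Ψ) at −3 (basophilic, AGC/CAMK),
* Group III — a phosphorylatable residue (S/T/Y, class Δ) at −3 and/or −2,
* Group IV  — everything else.

Each group is then subclustered by the direction of the 15-min response,
the speed at which half of the maximum response is reached, and the shape
of the time course, giving 15 leaf labels (I.A.1 ... IV.B).  Frequency
matrices over window positions support sequence-logo style summaries and
2x2 chi-square enrichment tests against a reference background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, PAD, PhosphoSite, SequenceWindow, TimeCourse

logger = logging.getLogger("kinbayes")

#: residue-class alphabet used for motif description
RESIDUE_CLASSES: dict[str, str] = {
    "Φ": "AFILMVW",   # non-polar
    "Δ": "STY",       # phosphorylatable polar
    "Θ": "DE",        # acidic
    "Ψ": "RKH",       # basic
    "Σ": "CNQ",       # non-phosphorylatable polar
    "P": "P",
    "G": "G",
}

#: residue -> class symbol (padding "J" has no class)
CLASS_OF: dict[str, str] = {
    aa: cls for cls, members in RESIDUE_CLASSES.items() for aa in members
}

BASIC = frozenset(RESIDUE_CLASSES["Ψ"])
PHOSPHO_POLAR = frozenset(RESIDUE_CLASSES["Δ"])

LEAF_LABELS = (
    "I.A.1", "I.A.2.a", "I.A.2.b", "I.A.2.c", "I.B",
    "II.A.1.a", "II.A.1.b", "II.B.1.a", "II.B.1.b", "II.B.2",
    "III.A", "III.B.1", "III.B.2", "IV.A", "IV.B",
)


class TieError(ValueError):
    """A direction call on an exactly-zero 15-min response."""


class UndefinedSpeedError(ValueError):
    """Speed classification of an all-zero time course."""


@dataclass(frozen=True)
class ClusterAssignment:
    site_id: str
    top_group: str
    leaf_label: str | None
    decision_trail: tuple[tuple[str, str], ...]
    unassigned_flag: bool = False

    def __post_init__(self) -> None:
        if self.leaf_label is not None and not self.leaf_label.startswith(
            self.top_group + "."
        ) and self.leaf_label != self.top_group:
            raise ValueError(
                f"leaf {self.leaf_label} inconsistent with group {self.top_group}"
            )
        if not self.decision_trail:
            raise ValueError("decision_trail must be non-empty")


# ---------------------------------------------------------------------------
# First-level partition and time-course descriptors
# ---------------------------------------------------------------------------


def first_level_partition(window: SequenceWindow) -> str:
    """Assign a window to Group I/II/III/IV by sequence context, in precedence."""
    if window.at(+1) == "P":
        return "I"
    if window.at(-3) in BASIC:
        return "II"
    if window.at(-3) in PHOSPHO_POLAR or window.at(-2) in PHOSPHO_POLAR:
        return "III"
    return "IV"


def direction_at_15(tc: TimeCourse) -> str:
    """'increased' or 'decreased' by the sign of the 15-min mean log2 ratio."""
    last = tc.log2_ratio[-1]
    if last == 0.0:
        raise TieError("15-min mean log2 ratio is exactly 0")
    return "increased" if last > 0 else "decreased"


def half_max_time(tc: TimeCourse) -> tuple[int, str]:
    """First time at which |ratio| reaches half its maximum, with a speed class.

    fast if that time is <= 1 min, slow if >= 5 min, intermediate otherwise.
    """
    ratios = np.abs(tc.ratio_array)
    peak = ratios.max()
    if peak == 0.0:
        raise UndefinedSpeedError("all-zero time course has no half-max time")
    for t, r in zip(tc.times, ratios):
        if r >= 0.5 * peak:
            speed = "fast" if t <= 1 else ("slow" if t >= 5 else "intermediate")
            return t, speed
    raise AssertionError("unreachable: the maximum itself satisfies the condition")


def pattern_class(tc: TimeCourse) -> str:
    """Shape class from signs of successive differences (baseline 0 at t=0).

    With d1 = x(1) - 0, d2 = x(2) - x(1), d3 = x(5) - x(2):
    monotonic            d1, d2, d3 <= 0
    dip_then_rise_at_5   d1 < 0, d2 <= 0, d3 > 0
    dip_then_rise_by_2   d1 < 0, d2 > 0
    rise_dip_rise        d1 > 0, d2 < 0, d3 > 0
    anything else        other
    """
    x = tc.ratio_array
    d1, d2, d3 = x[0] - 0.0, x[1] - x[0], x[2] - x[1]
    if d1 <= 0 and d2 <= 0 and d3 <= 0:
        return "monotonic"
    if d1 < 0 and d2 <= 0 and d3 > 0:
        return "dip_then_rise_at_5"
    if d1 < 0 and d2 > 0:
        return "dip_then_rise_by_2"
    if d1 > 0 and d2 < 0 and d3 > 0:
        return "rise_dip_rise"
    return "other"


# ---------------------------------------------------------------------------
# Leaf assignment
# ---------------------------------------------------------------------------


def _unassigned(site_id, group, trail) -> ClusterAssignment:
    return ClusterAssignment(site_id, group, None, tuple(trail), unassigned_flag=True)


def assign_leaf(
    window: SequenceWindow, tc: TimeCourse, top_group: str, site_id: str = ""
) -> ClusterAssignment:
    """Walk the deterministic subcluster tree for one site.

    Sites the leaf rules cannot cleanly place (e.g. a tie at 15 min, an
    'other' pattern where a specific shape is required) come back with
    ``unassigned_flag`` set and the decision trail explaining why.
    """
    trail: list[tuple[str, str]] = [("first_level", top_group)]

    try:
        direction = direction_at_15(tc)
    except TieError:
        trail.append(("direction_at_15", "tie"))
        logger.warning("site %s: 15-min ratio exactly 0; excluded from subclustering",
                       site_id)
        return _unassigned(site_id, top_group, trail)
    trail.append(("direction_at_15", direction))

    def leaf(label: str) -> ClusterAssignment:
        return ClusterAssignment(site_id, top_group, label, tuple(trail))

    if top_group == "I":
        if direction == "increased":
            return leaf("I.B")
        basic_56 = window.at(+5) in BASIC and window.at(+6) in BASIC
        trail.append(("basic_at_+5_and_+6", str(basic_56)))
        if basic_56:
            return leaf("I.A.1")
        pat = pattern_class(tc)
        trail.append(("pattern_class", pat))
        if pat == "monotonic":
            return leaf("I.A.2.a")
        if pat == "dip_then_rise_at_5":
            return leaf("I.A.2.b")
        if pat == "dip_then_rise_by_2":
            return leaf("I.A.2.c")
        return _unassigned(site_id, top_group, trail)

    if top_group == "II":
        basic_m2 = window.at(-2) in BASIC
        trail.append(("basic_at_-2", str(basic_m2)))
        if basic_m2:  # II.A
            if direction == "decreased":
                return _unassigned(site_id, top_group, trail)
            _, speed = half_max_time(tc)
            trail.append(("half_max_speed", speed))
            if speed == "slow":
                return leaf("II.A.1.a")
            if speed == "fast":
                return leaf("II.A.1.b")
            return _unassigned(site_id, top_group, trail)
        # II.B
        if direction == "increased":
            return leaf("II.B.2")
        pat = pattern_class(tc)
        trail.append(("pattern_class", pat))
        if pat == "rise_dip_rise":
            return leaf("II.B.1.a")
        if pat in ("dip_then_rise_by_2", "dip_then_rise_at_5"):
            return leaf("II.B.1.b")
        return _unassigned(site_id, top_group, trail)

    if top_group == "III":
        if direction == "increased":
            return leaf("III.A")
        basic_m1 = window.at(-1) in BASIC
        trail.append(("basic_at_-1", str(basic_m1)))
        return leaf("III.B.2" if basic_m1 else "III.B.1")

    if top_group == "IV":
        return leaf("IV.A" if direction == "increased" else "IV.B")

    raise ValueError(f"unknown top group {top_group!r}")


def assign_sites(sites: list[PhosphoSite]) -> list[ClusterAssignment]:
    """First-level partition plus leaf assignment for a list of sites."""
    return [
        assign_leaf(s.window, s.timecourse, first_level_partition(s.window), s.site_id)
        for s in sites
    ]


def assignments_to_frame(assignments: list[ClusterAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [a.site_id for a in assignments],
            "top_group": [a.top_group for a in assignments],
            "leaf_label": [a.leaf_label or "" for a in assignments],
            "unassigned": [a.unassigned_flag for a in assignments],
            "decision_trail": [
                ";".join(f"{rule}={out}" for rule, out in a.decision_trail)
                for a in assignments
            ],
        }
    )


# ---------------------------------------------------------------------------
# Frequency matrices, information content inputs, enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position symbol frequencies over non-padding residues.

    ``freqs`` is positions (-flank..+flank) x residues; each row sums to 1
    over the symbols observed at that position.  ``background`` holds the
    same statistic for a reference window set.
    """

    freqs: pd.DataFrame
    n: int
    background: pd.DataFrame | None = None

    def collapse_to_classes(self) -> pd.DataFrame:
        """Sum residue frequencies into the 7 residue-class symbols."""
        cols = self.freqs.columns.to_series().map(CLASS_OF)
        return self.freqs.T.groupby(cols).sum().T


def _position_frequencies(windows: list[SequenceWindow]) -> pd.DataFrame:
    flank = windows[0].flank
    positions = range(-flank, flank + 1)
    counts = pd.DataFrame(0.0, index=list(positions), columns=list(AMINO_ACIDS))
    for w in windows:
        if w.flank != flank:
            raise ValueError("all windows must share the same flank size")
        for pos in positions:
            aa = w.at(pos)
            if aa != PAD:
                counts.loc[pos, aa] += 1
    totals = counts.sum(axis=1)
    totals[totals == 0] = 1.0  # all-padding position: leave a zero row
    return counts.div(totals, axis=0)


def frequency_matrix(
    windows: list[SequenceWindow],
    background_windows: list[SequenceWindow] | None = None,
) -> FrequencyMatrix:
    """Position x residue frequencies, with an optional reference background."""
    if not windows:
        raise ValueError("need at least one window")
    freqs = _position_frequencies(windows)
    background = (
        _position_frequencies(background_windows) if background_windows else None
    )
    return FrequencyMatrix(freqs=freqs, n=len(windows), background=background)


def residue_background(windows: list[SequenceWindow]) -> pd.Series:
    """Overall residue frequencies across all positions of a window set."""
    counts = pd.Series(0.0, index=list(AMINO_ACIDS))
    for w in windows:
        for aa in w.residues:
            if aa != PAD:
                counts[aa] += 1
    return counts / counts.sum()


@dataclass(frozen=True)
class EnrichmentResult:
    chi_square: float
    p_value: float
    low_expected: bool = False


def enrichment_chisq(
    k_cluster: int, n_cluster: int, k_background: int, n_background: int,
    yates: bool = False,
) -> EnrichmentResult:
    """2x2 chi-square for symbol incidence in a cluster vs. a reference set.

    Continuity correction is off by default.  ``low_expected`` flags any
    expected cell below 1.
    """
    from scipy import stats

    if not (0 <= k_cluster <= n_cluster and 0 <= k_background <= n_background):
        raise ValueError("counts must not exceed their totals")
    if n_cluster <= 0 or n_background <= 0:
        raise ValueError("totals must be positive")
    obs = np.array(
        [[k_cluster, n_cluster - k_cluster],
         [k_background, n_background - k_background]],
        dtype=float,
    )
    col = obs.sum(axis=0)
    row = obs.sum(axis=1)
    total = obs.sum()
    if (col == 0).any():
        return EnrichmentResult(0.0, 1.0, low_expected=True)
    expected = np.outer(row, col) / total
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentResult(chi2, p, low_expected=bool((expected < 1).any()))
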