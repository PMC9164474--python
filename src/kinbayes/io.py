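"""Domain types, table readers/writers and validity filters.

The pipeline quantifies mono-phosphorylated peptides ("phosphosites") as
log2(treated/vehicle) ratios at 1, 2, 5 and 15 minutes after agonist
addition, with three biological replicates per time point.  Each site
carries a 13-mer sequence window: the phosphoacceptor (S, T or Y) at
position 0 flanked by six residues on each side, padded with the
placeholder ``J`` where the window runs past a protein terminus.

All tables are UTF-8 TSV with a header row; the kinase registry and
neighbor map are JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("kinbayes")

#: the four observation times, in minutes
TIMES: tuple[int, ...] = (1, 2, 5, 15)

#: standard 20-residue alphabet (one-letter codes)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: terminal-overhang placeholder
PAD = "J"

PHOSPHOACCEPTORS = frozenset("STY")


class SchemaError(ValueError):
    """A table is missing a required column or has an inconsistent layout."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


# ---------------------------------------------------------------------------
# Sequence windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceWindow:
    """A centralized sequence window around a phosphoacceptor.

    Positions are indexed -flank..+flank with the phosphoacceptor at 0;
    ``J`` marks positions beyond the protein termini and may occur only
    as a contiguous run at either end.
    """

    residues: str

    def __post_init__(self) -> None:
        seq = self.residues
        if len(seq) % 2 == 0 or len(seq) < 3:
            raise ValidationError(
                f"window length must be odd and >= 3, got {len(seq)}: {seq!r}"
            )
        bad = set(seq) - set(AMINO_ACIDS) - {PAD}
        if bad:
            raise ValidationError(f"unknown residues {sorted(bad)} in window {seq!r}")
        if self.center not in PHOSPHOACCEPTORS:
            raise ValidationError(
                f"position 0 must be S, T or Y, got {self.center!r} in {seq!r}"
            )
        core = seq.strip(PAD)
        if PAD in core:
            raise ValidationError(f"'J' padding must be terminal in {seq!r}")

    @property
    def flank(self) -> int:
        return len(self.residues) // 2

    @property
    def center(self) -> str:
        return self.residues[self.flank]

    def at(self, position: int) -> str:
        """Residue at a signed window position (0 = phosphoacceptor)."""
        if abs(position) > self.flank:
            raise IndexError(f"position {position} outside ±{self.flank}")
        return self.residues[self.flank + position]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.residues

    def __len__(self) -> int:
        return len(self.residues)


def centralize_site(
    protein_sequence: str, site_position: int, flank: int = 6
) -> SequenceWindow:
    """Extract the (2·flank+1)-mer centered on a 1-based protein position.

    Positions past the protein termini are padded with ``J``.
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1, got {flank}")
    n = len(protein_sequence)
    if not 1 <= site_position <= n:
        raise IndexError(
            f"site_position {site_position} outside protein of length {n}"
        )
    i = site_position - 1
    left = protein_sequence[max(0, i - flank) : i]
    right = protein_sequence[i + 1 : i + 1 + flank]
    residues = (
        PAD * (flank - len(left)) + left + protein_sequence[i] + right
        + PAD * (flank - len(right))
    )
    return SequenceWindow(residues)


def validate_site_match(window: SequenceWindow, reported_residue: str) -> bool:
    """True iff the window's position-0 residue equals the reported one."""
    return window.center == reported_residue


# ---------------------------------------------------------------------------
# Time courses and phosphosites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeCourse:
    """Mean and replicate log2(treated/vehicle) ratios at each time point.

    ``replicate_ratios`` has shape (n_times, n_replicates); ``log2_ratio``
    must equal its row means.  ``p_values`` are per-time significance
    values and may be filled in downstream.
    """

    times: tuple[int, ...]
    log2_ratio: tuple[float, ...]
    replicate_ratios: tuple[tuple[float, ...], ...]
    p_values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if list(self.times) != sorted(self.times) or len(set(self.times)) != len(
            self.times
        ):
            raise ValidationError(f"times must be strictly increasing: {self.times}")
        if len(self.log2_ratio) != len(self.times) or len(self.replicate_ratios) != len(
            self.times
        ):
            raise ValidationError("per-time arrays must match the time grid")
        for mean, reps in zip(self.log2_ratio, self.replicate_ratios):
            if len(reps) < 2:
                raise ValidationError("need >= 2 replicates per time point")
            if abs(mean - float(np.mean(reps))) > 1e-9:
                raise ValidationError(
                    f"mean {mean} does not match replicate average {np.mean(reps)}"
                )

    @property
    def ratio_array(self) -> np.ndarray:
        return np.asarray(self.log2_ratio, dtype=float)

    @property
    def replicate_array(self) -> np.ndarray:
        return np.asarray(self.replicate_ratios, dtype=float)


def timecourse_from_replicates(
    replicates: np.ndarray, times: tuple[int, ...] = TIMES
) -> TimeCourse:
    """Build a TimeCourse from a (n_times, n_reps) replicate array."""
    reps = np.asarray(replicates, dtype=float)
    return TimeCourse(
        times=tuple(times),
        log2_ratio=tuple(float(x) for x in reps.mean(axis=1)),
        replicate_ratios=tuple(tuple(float(v) for v in row) for row in reps),
    )


@dataclass(frozen=True)
class PhosphoSite:
    """One quantified mono-phosphosite with window and time course."""

    site_id: str
    gene_symbol: str
    residue: str
    position: int
    window: SequenceWindow
    timecourse: TimeCourse
    regulated: bool = False

    def __post_init__(self) -> None:
        if self.residue != self.window.center:
            raise ValidationError(
                f"{self.site_id}: reported residue {self.residue!r} does not match "
                f"window center {self.window.center!r}"
            )


# ---------------------------------------------------------------------------
# Kinase-substrate records and registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KinaseSubstrateRecord:
    """One experimentally mapped kinase → substrate-window event."""

    kinase: str
    substrate_window: SequenceWindow
    localization_probability: float
    has_site_determining_ions: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.localization_probability <= 1.0:
            raise ValidationError(
                f"localization probability {self.localization_probability} not in [0, 1]"
            )


def filter_substrate_records(
    records: list[KinaseSubstrateRecord], p_min: float = 0.75
) -> list[KinaseSubstrateRecord]:
    """Keep records with site-determining ions and localization P strictly above p_min."""
    if not 0.0 <= p_min <= 1.0:
        raise ValueError(f"p_min must be in [0, 1], got {p_min}")
    return [
        r
        for r in records
        if r.has_site_determining_ions and r.localization_probability > p_min
    ]


@dataclass(frozen=True)
class KinaseRegistry:
    """Ordered kinase symbols with family labels and a nearest-neighbor map.

    The reference registry holds the 521 known mammalian protein kinases;
    synthetic registries may be smaller.  The neighbor map imputes scores
    for kinases missing from an evidence table from their closest kinome
    neighbor.
    """

    kinases: tuple[str, ...]
    families: dict[str, str] = field(default_factory=dict)
    neighbor_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.kinases)) != len(self.kinases):
            raise ValidationError("kinase symbols must be unique")
        members = set(self.kinases)
        for k, nb in self.neighbor_map.items():
            if nb not in members:
                raise ValidationError(f"neighbor {nb!r} of {k!r} not in registry")
            if nb == k:
                raise ValidationError(f"kinase {k!r} is its own neighbor")

    def __len__(self) -> int:
        return len(self.kinases)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.kinases)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

_SITE_BASE_COLS = ["site_id", "gene_symbol", "residue", "position", "window"]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def sites_to_frame(sites: list[PhosphoSite]) -> pd.DataFrame:
    """Flatten PhosphoSite records to the TSV table layout."""
    rows = []
    for s in sites:
        row: dict[str, object] = {
            "site_id": s.site_id,
            "gene_symbol": s.gene_symbol,
            "residue": s.residue,
            "position": s.position,
            "window": s.window.residues,
            "regulated": s.regulated,
        }
        for t, mean, reps in zip(
            s.timecourse.times, s.timecourse.log2_ratio, s.timecourse.replicate_ratios
        ):
            row[f"ratio_{t}"] = mean
            for j, r in enumerate(reps, start=1):
                row[f"rep{t}_{j}"] = r
        rows.append(row)
    return pd.DataFrame(rows)


def write_phosphosite_table(path, sites: list[PhosphoSite]) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_phosphosite_table(path) -> list[PhosphoSite]:
    """Read a phosphosite TSV into PhosphoSite records.

    Rows whose window center disagrees with the reported residue are
    dropped with a warning rather than raising; duplicate site_ids raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    _require(df, _SITE_BASE_COLS, "phosphosite")
    if df.empty:
        return []
    dupes = df["site_id"][df["site_id"].duplicated()]
    if len(dupes):
        raise ValidationError(f"duplicate site_id(s): {sorted(set(dupes))}")
    rep_cols = {
        t: sorted(
            (c for c in df.columns if c.startswith(f"rep{t}_")),
            key=lambda c: int(c.split("_")[1]),
        )
        for t in TIMES
    }
    for t in TIMES:
        if f"ratio_{t}" not in df.columns:
            raise SchemaError(f"phosphosite table is missing column(s): ratio_{t}")
        if len(rep_cols[t]) < 2:
            raise SchemaError(f"phosphosite table needs >= 2 rep{t}_* columns")
    sites: list[PhosphoSite] = []
    for _, row in df.iterrows():
        try:
            window = SequenceWindow(str(row["window"]))
        except ValidationError as exc:
            raise ValidationError(f"site {row['site_id']}: {exc}") from exc
        if window.center != row["residue"]:
            logger.warning(
                "dropping site %s: residue %s does not match window center %s",
                row["site_id"], row["residue"], window.center,
            )
            continue
        reps = np.array([[row[c] for c in rep_cols[t]] for t in TIMES], dtype=float)
        tc = timecourse_from_replicates(reps)
        sites.append(
            PhosphoSite(
                site_id=str(row["site_id"]),
                gene_symbol=str(row["gene_symbol"]),
                residue=str(row["residue"]),
                position=int(row["position"]),
                window=window,
                timecourse=tc,
                regulated=bool(row.get("regulated", False)),
            )
        )
    return sites


def write_substrate_table(path, records: list[KinaseSubstrateRecord]) -> None:
    pd.DataFrame(
        {
            "kinase": [r.kinase for r in records],
            "substrate_window": [r.substrate_window.residues for r in records],
            "localization_probability": [r.localization_probability for r in records],
            "has_site_determining_ions": [r.has_site_determining_ions for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_substrate_table(path) -> list[KinaseSubstrateRecord]:
    df = pd.read_csv(path, sep="\t")
    _require(
        df,
        ["kinase", "substrate_window", "localization_probability",
         "has_site_determining_ions"],
        "kinase-substrate",
    )
    return [
        KinaseSubstrateRecord(
            kinase=str(row.kinase),
            substrate_window=SequenceWindow(str(row.substrate_window)),
            localization_probability=float(row.localization_probability),
            has_site_determining_ions=bool(row.has_site_determining_ions),
        )
        for row in df.itertuples()
    ]


def write_registry(path, registry: KinaseRegistry) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "kinases": list(registry.kinases),
                "families": registry.families,
                "neighbor_map": registry.neighbor_map,
            },
            fh,
            indent=1,
        )


def read_registry(path) -> KinaseRegistry:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    for key in ("kinases",):
        if key not in data:
            raise SchemaError(f"registry JSON is missing key {key!r}")
    return KinaseRegistry(
        kinases=tuple(data["kinases"]),
        families=dict(data.get("families", {})),
        neighbor_map=dict(data.get("neighbor_map", {})),
    )


def write_ranking_table(path, rankings: pd.DataFrame) -> None:
    """Write a (cluster, rank, kinase, family, posterior, probability_ratio) table."""
    _require(
        rankings,
        ["cluster", "rank", "kinase", "posterior", "probability_ratio"],
        "ranking",
    )
    rankings.to_csv(path, sep="\t", index=False)


def read_ranking_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["cluster", "rank", "kinase", "posterior", "probability_ratio"],
             "ranking")
    return df


def read_evidence_tables(paths: dict[str, str], registry: KinaseRegistry):
    """Assemble an EvidenceBundle from named files.

    ``paths`` keys: transcript, protein_a, protein_b (two-column TSV:
    kinase, value), sty (kinase, f_S, f_T, f_Y), kinase_profiles /
    substrate_profiles (wide TSV: first column the symbol, one column per
    fraction), activity (kinase, label), kinase_motifs (long TSV: kinase,
    position, residue, frequency), background (residue, frequency),
    pivots (JSON or YAML mapping step name → pivot spec).
    """
    from .bayes import ActivityAnnotation, EvidenceBundle  # avoid module cycle

    def _two_col(path, what) -> pd.Series:
        df = pd.read_csv(path, sep="\t")
        _require(df, ["kinase", "value"], what)
        return pd.Series(df["value"].values, index=df["kinase"].astype(str).values,
                         dtype=float)

    def _wide(path, what) -> pd.DataFrame:
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "symbol":
            raise SchemaError(f"{what} table is missing column(s): symbol")
        return df.set_index("symbol").astype(float)

    sty = pd.read_csv(paths["sty"], sep="\t")
    _require(sty, ["kinase", "f_S", "f_T", "f_Y"], "sty")
    sty = sty.set_index("kinase")[["f_S", "f_T", "f_Y"]].astype(float)

    act_df = pd.read_csv(paths["activity"], sep="\t")
    _require(act_df, ["kinase", "label"], "activity")
    activity = ActivityAnnotation(
        dict(zip(act_df["kinase"].astype(str), act_df["label"].astype(str)))
    )

    motifs_long = pd.read_csv(paths["kinase_motifs"], sep="\t")
    _require(motifs_long, ["kinase", "position", "residue", "frequency"],
             "kinase-motifs")
    kinase_motifs = {
        str(k): g.pivot_table(index="position", columns="residue",
                              values="frequency", fill_value=0.0)
        for k, g in motifs_long.groupby("kinase")
    }

    bg = pd.read_csv(paths["background"], sep="\t")
    _require(bg, ["residue", "frequency"], "background")
    background = pd.Series(bg["frequency"].values,
                           index=bg["residue"].astype(str).values, dtype=float)

    with open(paths["pivots"], encoding="utf-8") as fh:
        text = fh.read()
    try:
        pivots = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        pivots = yaml.safe_load(text)

    return EvidenceBundle(
        transcript=_two_col(paths["transcript"], "transcript"),
        protein_a=_two_col(paths["protein_a"], "protein-a"),
        protein_b=_two_col(paths["protein_b"], "protein-b"),
        sty=sty,
        kinase_profiles=_wide(paths["kinase_profiles"], "kinase-profiles"),
        substrate_profiles=_wide(paths["substrate_profiles"], "substrate-profiles"),
        activity=activity,
        kinase_motifs=kinase_motifs,
        background=background,
        pivots=dict(pivots),
        neighbor_map=dict(registry.neighbor_map),
    )
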