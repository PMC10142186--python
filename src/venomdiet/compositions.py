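"""Compositional venom and diet data: containers, cleaning, and diversity indices.

A venomic record is a relative-abundance profile over toxin protein families
(e.g. three-finger toxins, snake venom metalloproteinases), reported as percent
abundances by a proteomic or transcriptomic study.  A diet table is a per-species
tally of prey records at a chosen taxonomic level (prey family or prey order).
Both are compositions, so the same two diversity indices apply to each side:

* Shannon index  H = -sum_i p_i ln p_i   (nats; weighted toward richness)
* Gini-Simpson   D = 1 - sum_i p_i**2    (weighted toward evenness)

Cleaning follows the collation rules of quantitative venomics meta-analyses:
profiles whose reported percent total falls outside a plausibility window
(default 90-110%, allowing rounding slack around 100%) are discarded, and
species with fewer than five diet records are dropped because their diet
diversity would be dominated by isolated observations.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, ValidationError

logger = logging.getLogger(__name__)

def normalize_species_name(name: str) -> str:
    """Canonical species spelling: underscores to spaces, whitespace collapsed.

    Matches the taxon-label normalization used for tree tips, so table and
    tree names agree without a hand-built alias map in the common case."""
    return " ".join(str(name).replace("_", " ").split())


VENOM_COLUMNS = ["species", "record_id", "source", "method", "toxin_family", "percent_abundance"]
DIET_COLUMNS = ["species", "prey_family", "prey_order", "n_records"]
METHODS = frozenset({"proteome", "transcriptome"})
DIET_LEVELS = frozenset({"family", "order"})

#: Sum-to-one tolerance for normalized profiles.
NORMALIZATION_ATOL = 1e-9


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AbundanceProfile:
    """One venomic record: a composition over toxin families.

    ``components`` maps toxin-family label to abundance expressed as a
    fraction (reported percent / 100).  Fractions are *not* normalized at
    read time; :func:`clean_venom_profiles` renormalizes survivors so that
    they sum to one.  ``raw_total_percent`` keeps the as-published total for
    auditing the cleaning step.
    """

    species_id: str
    record_id: str
    source_id: str
    method: str
    components: dict[str, float]
    raw_total_percent: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise DataFormatError(
                f"record {self.record_id!r}: method must be one of {sorted(METHODS)}, "
                f"got {self.method!r}"
            )
        for label, value in self.components.items():
            if value < 0:
                raise ValidationError(
                    f"record {self.record_id!r}: negative abundance for {label!r}"
                )

    @property
    def abundances(self) -> np.ndarray:
        return np.asarray(list(self.components.values()), dtype=float)

    @property
    def is_normalized(self) -> bool:
        return math.isclose(self.abundances.sum(), 1.0, abs_tol=NORMALIZATION_ATOL)


@dataclass
class DietCountTable:
    """Prey-record counts for one species at one taxonomic level."""

    species_id: str
    level: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.level not in DIET_LEVELS:
            raise DataFormatError(f"diet level must be family|order, got {self.level!r}")
        for label, c in self.counts.items():
            if c < 1 or int(c) != c:
                raise ValidationError(
                    f"species {self.species_id!r}: prey count for {label!r} must be a "
                    f"positive integer, got {c!r}"
                )

    @property
    def total_records(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def proportions(self) -> np.ndarray:
        counts = np.asarray(list(self.counts.values()), dtype=float)
        return counts / counts.sum()


@dataclass
class CleaningReport:
    """Audit trail for a cleaning/filtering pass.

    Every removed record or species appears exactly once in ``removed_ids``
    as a ``(identifier, reason)`` pair.
    """

    n_input: int = 0
    n_removed_abundance: int = 0
    n_removed_diet: int = 0
    removed_ids: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_removed_abundance + self.n_removed_diet

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @staticmethod
    def merged(reports: Iterable["CleaningReport"]) -> "CleaningReport":
        out = CleaningReport()
        for r in reports:
            out.n_input += r.n_input
            out.n_removed_abundance += r.n_removed_abundance
            out.n_removed_diet += r.n_removed_diet
            out.removed_ids.extend(r.removed_ids)
        return out


# ---------------------------------------------------------------------------
# diversity indices
# ---------------------------------------------------------------------------

def _as_proportions(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("abundance vector must be one-dimensional")
    if np.any(arr < 0):
        raise ValidationError("abundance vector has negative entries")
    total = arr.sum()
    if total <= 0:
        raise ValidationError("abundance vector sums to zero")
    return arr / total


def shannon_index(p: Sequence[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i in nats.

    The vector is renormalized internally; zero components contribute 0
    (the limit p ln p -> 0).  Raises :class:`ValidationError` on negative
    entries or an all-zero vector.
    """
    q = _as_proportions(p)
    q = q[q > 0]
    return float(-(q * np.log(q)).sum())


def simpson_index(p: Sequence[float]) -> float:
    """Gini-Simpson diversity 1 - sum p_i**2 (probability two random draws differ)."""
    q = _as_proportions(p)
    return float(1.0 - (q * q).sum())


_INDEX_FUNCTIONS = {"shannon": shannon_index, "simpson": simpson_index}


def index_sampling_variance(counts: Sequence[float], index: str) -> float:
    """Delta-method sampling variance of a plug-in diversity index.

    For an index computed from multinomial counts (total N, proportions p),
    the first-order variance is  g' (diag(p) - p p') g / N  with g the index
    gradient: for Shannon  Var = (sum p (ln p)^2 - H^2) / N, for Gini-Simpson
    Var = 4 (sum p^3 - (sum p^2)^2) / N.  Used to propagate the uncertainty
    of a finite diet-record sample into the measurement-error regression.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0) or c.sum() <= 0:
        raise ValidationError("counts must be nonnegative with positive total")
    n_total = c.sum()
    p = c / n_total
    p = p[p > 0]
    if index == "shannon":
        h = -(p * np.log(p)).sum()
        var = float((p * np.log(p) ** 2).sum() - h**2)
    elif index == "simpson":
        s2 = (p**2).sum()
        var = float(4.0 * ((p**3).sum() - s2**2))
    else:
        raise DataFormatError(f"unknown index {index!r}; expected shannon|simpson")
    return max(var, 0.0) / n_total


def diversity(p: Sequence[float], index: str) -> float:
    """Dispatch to :func:`shannon_index` or :func:`simpson_index` by name."""
    try:
        fn = _INDEX_FUNCTIONS[index]
    except KeyError:
        raise DataFormatError(f"unknown index {index!r}; expected shannon|simpson") from None
    return fn(p)


# ---------------------------------------------------------------------------
# venom I/O and cleaning
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_venom_profiles(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> list[AbundanceProfile]:
    """Read a venom composition table into one profile per (species, record).

    Expects columns ``species, record_id, source, method, toxin_family,
    percent_abundance``.  Abundances are kept un-normalized;
    ``raw_total_percent`` records the published total.  ``aliases`` optionally
    maps species names in the file onto the names used by the tree/diet data.
    """
    df = _read_table(path, VENOM_COLUMNS)
    if df.empty:
        return []
    neg = df[df["percent_abundance"] < 0]
    if not neg.empty:
        row = neg.index[0]
        raise ValidationError(
            f"{path}: negative percent_abundance at row {row} "
            f"(record {df.loc[row, 'record_id']!r})"
        )
    dup = df.duplicated(subset=["record_id", "toxin_family"])
    if dup.any():
        row = df.index[dup][0]
        raise ValidationError(
            f"{path}: duplicate toxin_family {df.loc[row, 'toxin_family']!r} "
            f"within record {df.loc[row, 'record_id']!r}"
        )
    df = df.assign(species=df["species"].map(normalize_species_name))
    if aliases:
        df = df.assign(species=df["species"].map(lambda s: aliases.get(s, s)))

    profiles = []
    for (species, record_id), group in df.groupby(["species", "record_id"], sort=False):
        percents = group["percent_abundance"].to_numpy(dtype=float)
        profiles.append(
            AbundanceProfile(
                species_id=str(species),
                record_id=str(record_id),
                source_id=str(group["source"].iloc[0]),
                method=str(group["method"].iloc[0]),
                components=dict(zip(group["toxin_family"].astype(str), percents / 100.0)),
                raw_total_percent=float(percents.sum()),
            )
        )
    return profiles


def clean_venom_profiles(
    profiles: Sequence[AbundanceProfile],
    max_total_percent: float = 110.0,
    min_total_percent: float = 90.0,
) -> tuple[list[AbundanceProfile], CleaningReport]:
    """Drop implausible profiles and renormalize the survivors to sum to one.

    A profile is implausible when its published percent total exceeds
    ``max_total_percent`` (reason ``total_above_cap``) or falls below
    ``min_total_percent`` (reason ``total_below_floor``).  Renormalization
    divides every component by the profile total, so component ratios are
    preserved exactly.  Idempotent: cleaning an already-clean set changes
    nothing (a normalized profile has total 100%).
    """
    report = CleaningReport(n_input=len(profiles))
    retained: list[AbundanceProfile] = []
    for prof in profiles:
        total = prof.raw_total_percent
        if total > max_total_percent:
            report.n_removed_abundance += 1
            report.removed_ids.append((prof.record_id, "total_above_cap"))
            logger.info("removed record %s: total %.3f%% above cap", prof.record_id, total)
            continue
        if total < min_total_percent:
            report.n_removed_abundance += 1
            report.removed_ids.append((prof.record_id, "total_below_floor"))
            logger.info("removed record %s: total %.3f%% below floor", prof.record_id, total)
            continue
        current = prof.abundances.sum()
        components = {k: v / current for k, v in prof.components.items()}
        retained.append(
            AbundanceProfile(
                species_id=prof.species_id,
                record_id=prof.record_id,
                source_id=prof.source_id,
                method=prof.method,
                components=components,
                raw_total_percent=total,
            )
        )
    return retained, report


# ---------------------------------------------------------------------------
# diet aggregation and filtering
# ---------------------------------------------------------------------------

def read_diet_records(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a diet record table (columns ``species, prey_family, prey_order, n_records``)."""
    df = _read_table(path, DIET_COLUMNS)
    if not df.empty:
        df = df.assign(species=df["species"].map(normalize_species_name))
        if aliases:
            df = df.assign(species=df["species"].map(lambda s: aliases.get(s, s)))
    return df


def aggregate_diet(records: pd.DataFrame, level: str) -> list[DietCountTable]:
    """Aggregate per-row prey records into one count table per species.

    ``level`` selects the prey label column (``family`` -> ``prey_family``,
    ``order`` -> ``prey_order``).  Rows lacking a label at that level are
    dropped (logged); counts for duplicate labels are summed.
    """
    if level not in DIET_LEVELS:
        raise DataFormatError(f"diet level must be family|order, got {level!r}")
    col = "prey_family" if level == "family" else "prey_order"
    df = records.copy()
    if df.empty:
        return []
    bad = df[(df["n_records"] <= 0) | (df["n_records"] != df["n_records"].astype(int))]
    if not bad.empty:
        raise ValidationError(
            f"non-positive or non-integer n_records at row {bad.index[0]} "
            f"(species {bad['species'].iloc[0]!r})"
        )
    labelled = df[df[col].notna() & (df[col].astype(str).str.strip() != "")]
    n_dropped = len(df) - len(labelled)
    if n_dropped:
        logger.info("aggregate_diet(level=%s): dropped %d unlabelled rows", level, n_dropped)
    tables = []
    for species, group in labelled.groupby("species", sort=False):
        counts = group.groupby(group[col].astype(str))["n_records"].sum()
        tables.append(
            DietCountTable(
                species_id=str(species),
                level=level,
                counts={k: int(v) for k, v in counts.items()},
            )
        )
    return tables


def filter_diet(
    tables: Sequence[DietCountTable],
    min_items: int = 5,
) -> tuple[list[DietCountTable], CleaningReport]:
    """Drop species with fewer than ``min_items`` total prey records.

    Applied independently at each taxonomic level, so a species can survive
    the order-level filter while failing the family-level one.
    """
    report = CleaningReport(n_input=len(tables))
    retained = []
    for t in tables:
        if t.total_records < min_items:
            report.n_removed_diet += 1
            report.removed_ids.append((t.species_id, "too_few_prey_items"))
            logger.info(
                "removed species %s at %s level: %d prey records < %d",
                t.species_id, t.level, t.total_records, min_items,
            )
        else:
            retained.append(t)
    return retained, report


def count_prey_taxa(records: pd.DataFrame) -> tuple[int, int]:
    """Count distinct prey families and orders in a set of diet rows.

    Missing labels are ignored per level, so a row identified only to order
    still counts there.  Used for taxon-breadth comparisons such as the mamba
    diets (black mamba: eleven prey families in nine orders).
    """
    if records.empty:
        return (0, 0)

    def _distinct(col: str) -> int:
        vals = records[col].dropna().astype(str).str.strip()
        return int(vals[vals != ""].nunique())

    return (_distinct("prey_family"), _distinct("prey_order"))


# ---------------------------------------------------------------------------
# joined diversity table
# ---------------------------------------------------------------------------

def diversity_table(
    profiles: Sequence[AbundanceProfile],
    diet_tables_family: Sequence[DietCountTable] = (),
    diet_tables_order: Sequence[DietCountTable] = (),
) -> tuple[pd.DataFrame, list[str]]:
    """Join per-record venom diversity with per-species diet diversity.

    Diet diversity is computed once per species from its pooled records and
    replicated across every venomic record of that species.  Returns the
    joined frame (one row per venomic record; NaN where a diet level is
    unavailable for that species) and the list of venom-only species that
    were dropped because they have no diet data at either level.
    """
    diet_div: dict[str, dict[str, float]] = {}
    for tables, level in ((diet_tables_family, "family"), (diet_tables_order, "order")):
        for t in tables:
            d = diet_div.setdefault(t.species_id, {})
            d[f"diet_shannon_{level}"] = shannon_index(t.proportions)
            d[f"diet_simpson_{level}"] = simpson_index(t.proportions)

    rows, dropped = [], []
    for prof in profiles:
        diet = diet_div.get(prof.species_id)
        if diet is None:
            if prof.species_id not in dropped:
                dropped.append(prof.species_id)
            continue
        rows.append(
            {
                "record_id": prof.record_id,
                "species": prof.species_id,
                "source": prof.source_id,
                "method": prof.method,
                "venom_shannon": shannon_index(prof.abundances),
                "venom_simpson": simpson_index(prof.abundances),
                "diet_shannon_family": diet.get("diet_shannon_family", np.nan),
                "diet_simpson_family": diet.get("diet_simpson_family", np.nan),
                "diet_shannon_order": diet.get("diet_shannon_order", np.nan),
                "diet_simpson_order": diet.get("diet_simpson_order", np.nan),
            }
        )
    if dropped:
        logger.info("diversity_table: dropped %d species without diet data", len(dropped))
    columns = [
        "record_id", "species", "source", "method",
        "venom_shannon", "venom_simpson",
        "diet_shannon_family", "diet_simpson_family",
        "diet_shannon_order", "diet_simpson_order",
    ]
    return pd.DataFrame(rows, columns=columns), dropped


def analysis_dataset(table: pd.DataFrame, index: str, level: str) -> pd.DataFrame:
    """Extract the (species, x, y) rows for one regression: x is the species'
    diet diversity at ``level``, y the record's venom diversity, both under
    ``index``.  Records without a diet value at that level are excluded."""
    if index not in _INDEX_FUNCTIONS:
        raise DataFormatError(f"unknown index {index!r}")
    if level not in DIET_LEVELS:
        raise DataFormatError(f"unknown diet level {level!r}")
    xcol, ycol = f"diet_{index}_{level}", f"venom_{index}"
    sub = table[table[xcol].notna()]
    return pd.DataFrame(
        {"species": sub["species"], "x": sub[xcol], "y": sub[ycol]}
    ).reset_index(drop=True)
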