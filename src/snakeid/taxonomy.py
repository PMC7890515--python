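"""Resolving free-text snake identifications and ordinal accuracy scoring.

Participants in an identification challenge may answer with a scientific
binomen (``Bitis arietans``), a bare genus (``Bitis``), a family
(``Viperidae``), a common name (``puff adder``) or a listed synonym, or skip
the photo.  This module resolves such answers against a static taxonomy
snapshot and scores them on the four-point ordinal scale used throughout the
package:

    0 = incorrect or skipped, 1 = family correct, 2 = genus correct,
    3 = species binomen correct.

Matching is case- and whitespace-insensitive and synonym-aware; there is no
fuzzy spelling correction (answers in the study came from a drop-down list).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Canonical six-region vocabulary.
REGIONS = (
    "Africa",
    "Asia",
    "Australasia",
    "Europe",
    "NorthAmerica",
    "SouthAmerica",
)

_WS = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Casefold and collapse internal whitespace."""
    return _WS.sub(" ", raw.strip()).casefold()


def is_skip(raw) -> bool:
    """True for the skip marker: None / NaN / empty or blank string."""
    if raw is None:
        return True
    if isinstance(raw, float) and np.isnan(raw):
        return True
    return isinstance(raw, str) and raw.strip() == ""


@dataclass(frozen=True)
class TaxonRecord:
    """One species in the taxonomy snapshot."""

    binomen: str
    genus: str
    family: str
    synonyms: tuple[str, ...] = ()
    common_names: tuple[str, ...] = ()
    is_mivs: bool = False  # WHO category 1/2 medically important venomous snake
    regions: frozenset = frozenset()

    def __post_init__(self):
        if not self.binomen.startswith(self.genus + " "):
            raise ValueError(
                f"binomen {self.binomen!r} does not begin with genus {self.genus!r}"
            )
        if not self.family:
            raise ValueError(f"{self.binomen}: family must be non-empty")
        unknown = set(self.regions) - set(REGIONS)
        if unknown:
            raise ValueError(f"{self.binomen}: unknown region(s) {sorted(unknown)}")


@dataclass(frozen=True)
class NameMatch:
    """Normal form of a resolved answer.

    ``rank`` is the most specific taxonomic level the raw string denotes;
    canonical fields are filled down to that level and ``None`` below it.
    """

    rank: str  # 'species' | 'genus' | 'family' | 'none'
    binomen: Optional[str] = None
    genus: Optional[str] = None
    family: Optional[str] = None

    def __post_init__(self):
        if self.rank not in ("species", "genus", "family", "none"):
            raise ValueError(f"invalid rank {self.rank!r}")
        if self.rank == "species" and not (self.binomen and self.genus and self.family):
            raise ValueError("species-rank match must set all canonical fields")
        if self.rank == "none" and (self.binomen or self.genus or self.family):
            raise ValueError("rank=none match must leave canonical fields unset")


NO_MATCH = NameMatch("none")


class Taxonomy:
    """Validated taxonomy snapshot with name-resolution lookup tables."""

    def __init__(self, records: Iterable[TaxonRecord]):
        self.records: tuple[TaxonRecord, ...] = tuple(records)
        if not self.records:
            raise ValueError("taxonomy is empty")
        self._by_binomen: dict[str, TaxonRecord] = {}
        self._species_names: dict[str, TaxonRecord] = {}  # binomen+synonyms+commons
        self._genus_family: dict[str, tuple[str, str]] = {}
        self._families: dict[str, str] = {}

        for rec in self.records:
            key = normalize_name(rec.binomen)
            if key in self._by_binomen:
                raise ValueError(f"duplicate binomen {rec.binomen!r}")
            self._by_binomen[key] = rec

        for rec in self.records:
            for name in (rec.binomen, *rec.synonyms, *rec.common_names):
                key = normalize_name(name)
                other = self._species_names.get(key)
                if other is not None and other.binomen != rec.binomen:
                    raise ValueError(
                        f"name {name!r} maps to both {other.binomen!r} and {rec.binomen!r}"
                    )
                self._species_names[key] = rec
            gkey = normalize_name(rec.genus)
            known = self._genus_family.get(gkey)
            if known is not None and known[1] != rec.family:
                raise ValueError(
                    f"genus {rec.genus!r} listed in families {known[1]!r} and {rec.family!r}"
                )
            self._genus_family[gkey] = (rec.genus, rec.family)
            self._families[normalize_name(rec.family)] = rec.family

        self._genus_mivs = {}
        self._family_mivs = {}
        for rec in self.records:
            self._genus_mivs[rec.genus] = self._genus_mivs.get(rec.genus, False) or rec.is_mivs
            self._family_mivs[rec.family] = (
                self._family_mivs.get(rec.family, False) or rec.is_mivs
            )

    # -- lookups -----------------------------------------------------------
    def record(self, binomen: str) -> TaxonRecord:
        try:
            return self._by_binomen[normalize_name(binomen)]
        except KeyError:
            raise KeyError(f"species {binomen!r} not in taxonomy") from None

    def __contains__(self, binomen: str) -> bool:
        return normalize_name(binomen) in self._by_binomen

    def __len__(self) -> int:
        return len(self.records)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(sorted(set(r.family for r in self.records)))

    def species_in_genus(self, genus: str) -> list[TaxonRecord]:
        return [r for r in self.records if r.genus == genus]

    def genera_in_family(self, family: str) -> list[str]:
        return sorted(set(r.genus for r in self.records if r.family == family))

    def genus_is_mivs(self, genus: str) -> bool:
        """A genus counts as MIVS iff it contains at least one MIVS species."""
        return self._genus_mivs.get(genus, False)

    def family_is_mivs(self, family: str) -> bool:
        return self._family_mivs.get(family, False)


def resolve_name(raw, taxonomy: Taxonomy) -> NameMatch:
    """Resolve a free-text answer (or skip marker) to its taxonomic normal form.

    Species-level names (binomina, synonyms, common names) are tried first,
    then genus names, then family names; unmatched strings resolve to
    ``rank='none'`` (a valid outcome, not an error).
    """
    if is_skip(raw):
        return NO_MATCH
    key = normalize_name(str(raw))
    rec = taxonomy._species_names.get(key)
    if rec is not None:
        return NameMatch("species", rec.binomen, rec.genus, rec.family)
    gf = taxonomy._genus_family.get(key)
    if gf is not None:
        return NameMatch("genus", None, gf[0], gf[1])
    fam = taxonomy._families.get(key)
    if fam is not None:
        return NameMatch("family", None, None, fam)
    return NO_MATCH


def score_response(match: NameMatch, true_species: str, taxonomy: Taxonomy) -> int:
    """Four-point ordinal accuracy of a resolved answer against the truth.

    3 iff the canonical binomen (after synonym resolution) equals the true
    species; else 2 iff the genus matches; else 1 iff the family matches;
    else 0.  Answers above species level can never score 3.
    """
    truth = taxonomy.record(true_species)
    if match.rank == "none":
        return 0
    if match.binomen is not None and match.binomen == truth.binomen:
        return 3
    if match.genus is not None and match.genus == truth.genus:
        return 2
    if match.family is not None and match.family == truth.family:
        return 1
    return 0


def score_mivs(match: NameMatch, true_species: str, taxonomy: Taxonomy) -> bool:
    """Whether the answer is correct about medical importance.

    True iff the MIVS status of the answered taxon equals that of the true
    species.  Genus- and family-level answers take the status of the higher
    taxon (MIVS iff it contains at least one MIVS species); skips and
    unresolvable answers count as incorrect.
    """
    truth = taxonomy.record(true_species)
    if match.rank == "none":
        return False
    if match.rank == "species":
        answered = taxonomy.record(match.binomen).is_mivs
    elif match.rank == "genus":
        answered = taxonomy.genus_is_mivs(match.genus)
    else:
        answered = taxonomy.family_is_mivs(match.family)
    return answered == truth.is_mivs


def compute_taxa_repeat(responses: pd.DataFrame) -> pd.Series:
    """Count of earlier photos of the same species each participant has seen.

    Requires columns ``participant_id``, ``photo_id``, ``true_species`` and
    ``order_index`` (presentation order within participant).  The first
    exposure of a species is 0.  Returns a Series aligned with the input index.
    """
    required = {"participant_id", "photo_id", "true_species", "order_index"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"responses missing columns: {sorted(missing)}")
    dup = responses.duplicated(subset=["participant_id", "photo_id", "order_index"])
    if dup.any():
        raise ValueError(
            f"duplicated (participant, photo, order) rows at positions "
            f"{list(responses.index[dup])[:10]}"
        )
    dup_order = responses.duplicated(subset=["participant_id", "order_index"])
    if dup_order.any():
        raise ValueError("presentation order is not unique within participant")
    ordered = responses.sort_values(["participant_id", "order_index"], kind="mergesort")
    repeat = ordered.groupby(["participant_id", "true_species"], sort=False).cumcount()
    return repeat.reindex(responses.index).rename("taxa_repeat")


def score_table(responses: pd.DataFrame, taxonomy: Taxonomy) -> pd.DataFrame:
    """Resolve and score a whole response table.

    Adds columns ``answer_rank``, ``answer_binomen``, ``answer_genus``,
    ``answer_family``, ``score`` and ``mivs_correct`` (plus ``family`` — the
    family of the true species, needed downstream by the design matrix).
    """
    out = responses.copy()
    cache: dict[str, NameMatch] = {}

    ranks, binomina, genera, families, scores, mivs = [], [], [], [], [], []
    for raw, true_sp in zip(out["answer_raw"], out["true_species"]):
        key = "" if is_skip(raw) else normalize_name(str(raw))
        match = cache.get(key)
        if match is None:
            match = resolve_name(raw, taxonomy)
            cache[key] = match
        ranks.append(match.rank)
        binomina.append(match.binomen)
        genera.append(match.genus)
        families.append(match.family)
        scores.append(score_response(match, true_sp, taxonomy))
        mivs.append(score_mivs(match, true_sp, taxonomy))

    out["answer_rank"] = ranks
    out["answer_binomen"] = binomina
    out["answer_genus"] = genera
    out["answer_family"] = families
    out["score"] = np.asarray(scores, dtype=np.int64)
    out["mivs_correct"] = np.asarray(mivs, dtype=bool)
    out["family"] = [taxonomy.record(sp).family for sp in out["true_species"]]
    if "taxa_repeat" not in out.columns:
        out["taxa_repeat"] = compute_taxa_repeat(out)
    return out
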