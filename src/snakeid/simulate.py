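"""Forward simulation of an identification challenge.

Generates response tables with exactly the latent structure the graded
response model assumes — participant abilities, photo- and species-level
difficulty/discrimination pairs, fixed effects for family, region,
home-region match and within-challenge learning — plus the ground-truth
parameters, for recovery testing.  Defaults mirror the full-scale study
conditions: 250 participants, 100 species x 10 photos across 9 families and
6 global regions, with effect sizes at the reference posterior medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import reference
from .grm import DesignSpec, FAMILIES, build_design, category_probs
from .taxonomy import REGIONS, Taxonomy, TaxonRecord, compute_taxa_repeat

#: Species per family, shaped like the challenge (colubrid-heavy, small
#: obscure families).  Every family gets >=2 genera and every genus >=2
#: species so that genus- and family-level wrong answers are realizable.
DEFAULT_FAMILY_ALLOCATION = {
    "Colubridae": 32,
    "Viperidae": 22,
    "Elapidae": 16,
    "Boidae": 6,
    "Pythonidae": 6,
    "Lamprophiidae": 6,
    "Cylindrophiidae": 4,
    "Typhlopidae": 4,
    "Leptotyphlopidae": 4,
}

#: Share of species per global region (photos carry their species' region).
DEFAULT_REGION_WEIGHTS = {
    "Africa": 0.20,
    "Asia": 0.22,
    "Australasia": 0.12,
    "Europe": 0.10,
    "NorthAmerica": 0.20,
    "SouthAmerica": 0.16,
}

#: Participant home-region mix observed in the challenge.
DEFAULT_HOME_WEIGHTS = {
    "NorthAmerica": 0.50,
    "Europe": 0.22,
    "Africa": 0.10,
    "Asia": 0.10,
    "SouthAmerica": 0.04,
    "Australasia": 0.04,
}

#: Families whose genera are flagged medically important in the synthetic
#: taxonomy (front-fanged lineages), mirroring the real MIVS structure.
MIVS_FAMILIES = ("Viperidae", "Elapidae")


@dataclass
class SimConfig:
    """Generator settings; defaults are the study conditions."""

    n_participants: int = 250
    n_species: int = 100
    photos_per_species: int = 10
    n_distractors: int = 100          # single-photo decoys, excluded from analysis
    photos_per_participant: int = 400  # photos answered by each participant
    family_allocation: dict = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_ALLOCATION))
    region_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS))
    home_weights: dict = field(default_factory=lambda: dict(DEFAULT_HOME_WEIGHTS))
    tau: tuple = tuple(reference.THRESHOLDS)
    family_effects: dict = field(default_factory=lambda: dict(reference.FAMILY_EFFECTS))
    region_effects: dict = field(default_factory=lambda: dict(reference.REGION_EFFECTS))
    home_effect: float = reference.HOME_REGION_EFFECT
    home_interactions: dict = field(
        default_factory=lambda: dict(reference.HOME_REGION_INTERACTIONS))
    taxa_repeat_effect: float = reference.TAXA_REPEAT_EFFECT
    quality_effect: float = 0.0       # quality has no generative effect by default
    delta0: float = reference.DISCRIMINATION
    sd_participant: float = reference.SD_PARTICIPANT
    sd_photo_b: float = reference.SD_PHOTO_DIFFICULTY
    sd_photo_d: float = reference.SD_PHOTO_DISCRIMINATION
    cor_photo: float = reference.COR_PHOTO
    sd_species_b: float = reference.SD_SPECIES_DIFFICULTY
    sd_species_d: float = reference.SD_SPECIES_DISCRIMINATION
    cor_species: float = reference.COR_SPECIES
    quality_high_first: bool = False  # optional high-before-low presentation
    seed: int = 0

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        if tau.size != 3 or not np.all(np.diff(tau) > 0):
            raise ValueError("tau must be 3 strictly increasing thresholds")
        for name in ("sd_participant", "sd_photo_b", "sd_photo_d",
                     "sd_species_b", "sd_species_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cor_photo", "cor_species"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if sum(self.family_allocation.values()) != self.n_species:
            raise ValueError("family_allocation must sum to n_species")
        unknown = set(self.family_allocation) - set(FAMILIES)
        if unknown:
            raise ValueError(f"family_allocation has unknown families {sorted(unknown)}")
        if self.n_participants < 1 or self.photos_per_species < 1:
            raise ValueError("n_participants and photos_per_species must be >= 1")

    @property
    def max_identifications(self) -> int:
        """Largest number of photos any one participant could identify."""
        return self.n_species * self.photos_per_species + self.n_distractors


@dataclass
class SimTruth:
    """Latent parameters behind one simulated challenge."""

    theta: pd.Series              # by participant_id
    photo_effects: pd.DataFrame   # photo_id -> b, d
    species_effects: pd.DataFrame  # binomen -> b, d
    config: SimConfig

    def save(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.theta.rename("theta").to_csv(directory / "theta.csv")
        self.photo_effects.to_csv(directory / "photo_effects.csv")
        self.species_effects.to_csv(directory / "species_effects.csv")
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in asdict(self.config).items()}
        import json
        (directory / "config.json").write_text(json.dumps(cfg, indent=1))


def _bivariate(rng, n, sd1, sd2, rho):
    z = rng.standard_normal((2, n))
    b = sd1 * z[0]
    d = sd2 * (rho * z[0] + np.sqrt(max(0.0, 1 - rho**2)) * z[1])
    return b, d


def synthetic_taxonomy(config: Optional[SimConfig] = None,
                       seed: Optional[int] = None) -> Taxonomy:
    """Build a schematic taxonomy matching the generator's allocations.

    Genus and species names are synthetic placeholders; genera hold 2-5
    species, ~10% of species get a synonym and ~20% a common name so the
    name-resolution path is exercised end to end.  All genera in the
    front-fanged families are flagged MIVS, plus one burrowing-asp-like
    genus of Lamprophiidae.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    regions = list(config.region_weights)
    w = np.array([config.region_weights[r] for r in regions], dtype=float)
    w = w / w.sum()

    records = []
    for family, n_sp in config.family_allocation.items():
        stem = family[:4].capitalize()
        # split species into genera of >=2
        remaining = n_sp
        genus_sizes = []
        while remaining > 0:
            size = int(rng.integers(2, 6))
            if remaining - size < 2 and remaining - size != 0:
                size = remaining
            size = min(size, remaining)
            genus_sizes.append(size)
            remaining -= size
        if len(genus_sizes) < 2 and n_sp >= 4:  # ensure >=2 genera
            genus_sizes = [n_sp // 2, n_sp - n_sp // 2]
        for g, size in enumerate(genus_sizes, start=1):
            genus = f"{stem}ophis{g}"
            mivs_genus = family in MIVS_FAMILIES or (
                family == "Lamprophiidae" and g == 1)
            for k in range(1, size + 1):
                binomen = f"{genus} species{k}"
                synonyms = ()
                if rng.random() < 0.10:
                    synonyms = (f"{genus}us species{k}",)
                common = ()
                if rng.random() < 0.20:
                    common = (f"{stem.lower()} snake {g}-{k}",)
                region = regions[rng.choice(len(regions), p=w)]
                records.append(TaxonRecord(
                    binomen=binomen, genus=genus, family=family,
                    synonyms=synonyms, common_names=common,
                    is_mivs=bool(mivs_genus), regions=frozenset([region]),
                ))
    return Taxonomy(records)


def simulate_challenge(
    config: Optional[SimConfig] = None,
    taxonomy: Optional[Taxonomy] = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate scored responses from the generative GRM.

    Returns a response table (one row per participant x answered photo, with
    ordinal ``score``) and the latent ``SimTruth``.  All randomness flows
    from ``config.seed``; identical seeds give identical tables.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    if taxonomy is None:
        taxonomy = synthetic_taxonomy(config, seed=config.seed)
    species = [r for r in taxonomy.records]
    if len(species) != config.n_species:
        raise ValueError(
            f"taxonomy has {len(species)} species, config expects {config.n_species}")

    # photos: photos_per_species per species, from the species' region
    photo_rows = []
    for rec in species:
        region = sorted(rec.regions)[0] if rec.regions else "Africa"
        for k in range(config.photos_per_species):
            quality = "high" if k < config.photos_per_species / 2 else "low"
            photo_rows.append((f"{rec.binomen}|{k + 1}", rec.binomen, rec.genus,
                               rec.family, region, quality))
    photos = pd.DataFrame(photo_rows, columns=[
        "photo_id", "true_species", "genus", "family", "photo_region", "quality"])
    n_photos = len(photos)

    # latent structure
    theta = config.sd_participant * rng.standard_normal(config.n_participants)
    pb, pd_ = _bivariate(rng, n_photos, config.sd_photo_b,
                         config.sd_photo_d, config.cor_photo)
    sb, sd_ = _bivariate(rng, len(species), config.sd_species_b,
                         config.sd_species_d, config.cor_species)
    sp_index = {rec.binomen: i for i, rec in enumerate(species)}

    homes = list(config.home_weights)
    hw = np.array([config.home_weights[h] for h in homes], dtype=float)
    hw = hw / hw.sum()
    participant_ids = [f"P{j + 1:04d}" for j in range(config.n_participants)]
    home_region = [homes[i] for i in rng.choice(len(homes),
                                                config.n_participants, p=hw)]

    fam_eff = photos["family"].map(config.family_effects).to_numpy(dtype=float)
    reg_eff = photos["photo_region"].map(config.region_effects).to_numpy(dtype=float)
    qual_eff = np.where(photos["quality"].to_numpy() == "low",
                        config.quality_effect, 0.0)
    photo_base = fam_eff + reg_eff + qual_eff + pb + sb[
        photos["true_species"].map(sp_index).to_numpy()]
    photo_logalpha = config.delta0 + pd_ + sd_[
        photos["true_species"].map(sp_index).to_numpy()]
    tau = np.asarray(config.tau, dtype=float)

    n_answered = min(config.photos_per_participant, n_photos)
    sp_codes = photos["true_species"].map(sp_index).to_numpy()
    quality_rank = (photos["quality"].to_numpy() == "low").astype(int)

    frames = []
    for j, pid in enumerate(participant_ids):
        chosen = rng.choice(n_photos, size=n_answered, replace=False)
        if config.quality_high_first:
            # stable shuffle within quality tier: high-quality photos first
            order_key = rng.random(n_answered) + quality_rank[chosen]
            chosen = chosen[np.argsort(order_key, kind="stable")]
        else:
            rng.shuffle(chosen)
        # running count of earlier photos of the same species
        codes = sp_codes[chosen]
        repeat = np.zeros(n_answered, dtype=np.int64)
        seen: dict[int, int] = {}
        for t, c in enumerate(codes):
            repeat[t] = seen.get(c, 0)
            seen[c] = repeat[t] + 1

        home_match = photos["photo_region"].to_numpy()[chosen] == home_region[j]
        eta = (photo_base[chosen] + theta[j]
               + config.home_effect * home_match
               + home_match * np.array([
                   config.home_interactions.get(r, 0.0)
                   for r in photos["photo_region"].to_numpy()[chosen]])
               + config.taxa_repeat_effect * repeat)
        alpha = np.exp(photo_logalpha[chosen])
        probs = category_probs(eta, alpha, tau)
        u = rng.random(n_answered)
        score = (u[:, None] > np.cumsum(probs, axis=1)[:, :3]).sum(axis=1)

        frames.append(pd.DataFrame({
            "participant_id": pid,
            "home_region": home_region[j],
            "photo_id": photos["photo_id"].to_numpy()[chosen],
            "true_species": photos["true_species"].to_numpy()[chosen],
            "family": photos["family"].to_numpy()[chosen],
            "photo_region": photos["photo_region"].to_numpy()[chosen],
            "quality": photos["quality"].to_numpy()[chosen],
            "order_index": np.arange(n_answered),
            "taxa_repeat": repeat,
            "score": score,
        }))

    responses = pd.concat(frames, ignore_index=True)
    truth = SimTruth(
        theta=pd.Series(theta, index=participant_ids, name="theta"),
        photo_effects=pd.DataFrame(
            {"b": pb, "d": pd_}, index=photos["photo_id"]),
        species_effects=pd.DataFrame(
            {"b": sb, "d": sd_}, index=[r.binomen for r in species]),
        config=config,
    )
    return responses, truth


def attach_answer_strings(
    responses: pd.DataFrame,
    taxonomy: Taxonomy,
    seed: int,
    skip_probability: float = 0.5,
) -> pd.DataFrame:
    """Fill ``answer_raw`` with name strings consistent with each score.

    Score 3 rows get the true binomen (occasionally a listed synonym); score
    2 a uniformly chosen congener; score 1 a confamilial from another genus;
    score 0 a skip (with ``skip_probability``) or an extra-familial species.
    Re-scoring the emitted strings reproduces the ordinal scores exactly.
    """
    rng = np.random.default_rng(seed)
    by_genus: dict[str, list[str]] = {}
    by_family_genera: dict[str, list[str]] = {}
    all_species = [r.binomen for r in taxonomy.records]
    families = {}
    for r in taxonomy.records:
        by_genus.setdefault(r.genus, []).append(r.binomen)
        by_family_genera.setdefault(r.family, [])
        if r.genus not in by_family_genera[r.family]:
            by_family_genera[r.family].append(r.genus)
        families[r.binomen] = r.family

    answers = []
    for row in responses.itertuples(index=False):
        rec = taxonomy.record(row.true_species)
        score = int(row.score)
        if score == 3:
            if rec.synonyms and rng.random() < 0.1:
                answers.append(rec.synonyms[0])
            else:
                answers.append(rec.binomen)
        elif score == 2:
            congeners = [s for s in by_genus[rec.genus] if s != rec.binomen]
            if not congeners:
                raise ValueError(
                    f"cannot realize score 2: genus {rec.genus} has one species")
            answers.append(congeners[rng.integers(len(congeners))])
        elif score == 1:
            other_genera = [g for g in by_family_genera[rec.family] if g != rec.genus]
            if not other_genera:
                raise ValueError(
                    f"cannot realize score 1: family {rec.family} has one genus")
            genus = other_genera[rng.integers(len(other_genera))]
            pool = by_genus[genus]
            answers.append(pool[rng.integers(len(pool))])
        else:
            if rng.random() < skip_probability:
                answers.append("")
            else:
                pool = [s for s in all_species if families[s] != rec.family]
                if not pool:
                    answers.append("")
                else:
                    answers.append(pool[rng.integers(len(pool))])
    out = responses.copy()
    out["answer_raw"] = answers
    return out
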