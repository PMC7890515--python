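"""File readers/writers, validated run configuration and the pipeline driver.

All tabular formats are plain delimited text (comma default, header row);
list-valued taxonomy fields are pipe-separated.  Region labels are
normalized to the canonical six-region vocabulary through an alias map —
unknown labels are errors, not guesses.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .grm import build_design, convergence_diagnostics, fit_grm
from .selection import (compare_models, heldout_mae, bayes_r2, model_grid,
                        psis_loo, split_train_test)
from .summaries import (genus_confusion, photo_consensus_stats, quintile_table)
from .taxonomy import (REGIONS, Taxonomy, TaxonRecord, score_table)

log = logging.getLogger("snakeid")

REGION_ALIASES = {
    "africa": "Africa",
    "asia": "Asia",
    "australasia": "Australasia",
    "australia": "Australasia",
    "oceania": "Australasia",
    "australia/oceania": "Australasia",
    "europe": "Europe",
    "northamerica": "NorthAmerica",
    "north america": "NorthAmerica",
    "southamerica": "SouthAmerica",
    "south america": "SouthAmerica",
}

RESPONSE_COLUMNS = [
    "participant_id", "home_region", "photo_id", "true_species",
    "photo_region", "quality", "order_index", "answer_raw",
]


def normalize_region(label: str) -> str:
    key = str(label).strip().lower()
    if key not in REGION_ALIASES:
        raise ValueError(f"unknown region label {label!r}")
    return REGION_ALIASES[key]


def read_taxonomy(path, sep: str = ",") -> Taxonomy:
    """Load a taxonomy table (pipe-separated list fields)."""
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    required = {"binomen", "genus", "family", "synonyms", "common_names",
                "is_mivs", "regions"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy file missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(TaxonRecord(
            binomen=row.binomen,
            genus=row.genus,
            family=row.family,
            synonyms=tuple(s for s in str(row.synonyms).split("|") if s),
            common_names=tuple(s for s in str(row.common_names).split("|") if s),
            is_mivs=str(row.is_mivs).strip().lower() in ("1", "true", "t", "yes"),
            regions=frozenset(normalize_region(r)
                              for r in str(row.regions).split("|") if r),
        ))
    return Taxonomy(records)


def write_taxonomy(taxonomy: Taxonomy, path, sep: str = ",") -> None:
    rows = [{
        "binomen": r.binomen, "genus": r.genus, "family": r.family,
        "synonyms": "|".join(r.synonyms),
        "common_names": "|".join(r.common_names),
        "is_mivs": str(r.is_mivs),
        "regions": "|".join(sorted(r.regions)),
    } for r in taxonomy.records]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_responses(path, sep: str = ",",
                   column_map: Optional[dict] = None) -> pd.DataFrame:
    """Load and validate a response table.

    ``column_map`` renames source columns to the canonical schema before
    validation.  Malformed rows are rejected with their (1-based, header
    included) line numbers; duplicate (participant, photo) pairs and unknown
    regions are explicit errors.
    """
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str, "photo_id": str},
                     keep_default_na=False, na_values=[])
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"response file missing columns: {sorted(missing)}")

    lineno = df.index.to_numpy() + 2  # header is line 1
    for col in ("home_region", "photo_region"):
        normalized = []
        for i, v in zip(lineno, df[col]):
            try:
                normalized.append(normalize_region(v))
            except ValueError as e:
                raise ValueError(f"line {i}: {e}") from None
        df[col] = normalized

    bad_order = pd.to_numeric(df["order_index"], errors="coerce").isna()
    if bad_order.any():
        raise ValueError(
            f"non-integer order_index at line(s) "
            f"{[int(i) for i in lineno[bad_order]][:10]}")
    df["order_index"] = df["order_index"].astype(np.int64)

    dup = df.duplicated(subset=["participant_id", "photo_id"], keep=False)
    if dup.any():
        raise ValueError(
            "duplicate (participant, photo) rows at lines "
            f"{[int(i) for i in lineno[dup]][:10]}")
    return df


def write_responses(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    responses: str
    taxonomy: str
    output_dir: str
    seed: int
    min_photos: int = 80
    train_fraction: float = 0.8
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    max_leapfrog: int = 24
    grid: Optional[list] = None       # model names to fit; None = all six
    filter_min_photos: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (self.responses, self.taxonomy):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Score -> filter -> split -> fit grid -> compare -> summarize.

    Each stage logs record counts; outputs land in ``config.output_dir``
    with a manifest carrying the config hash and seed.  Identical
    config+seed reruns produce identical tables.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")

    taxonomy = read_taxonomy(config.taxonomy)
    responses = read_responses(config.responses)
    log.info("stage=read responses=%d species=%d", len(responses), len(taxonomy))

    scored = score_table(responses, taxonomy)
    scored.to_csv(out / "scored.csv", index=False)
    log.info("stage=score rows=%d mean_score=%.3f",
             len(scored), scored["score"].mean())

    if config.filter_min_photos:
        counts = scored.groupby("participant_id")["photo_id"].size()
        keep = counts[counts >= config.min_photos].index
        n_before = scored["participant_id"].nunique()
        scored = scored[scored["participant_id"].isin(keep)].reset_index(drop=True)
        log.info("stage=filter min_photos=%d participants %d -> %d",
                 config.min_photos, n_before, len(keep))
        if scored.empty:
            raise RuntimeError("stage=filter: no participants pass the threshold")

    train, test = split_train_test(scored, config.train_fraction, seed=config.seed)
    train.to_csv(out / "train.csv", index=False)
    test.to_csv(out / "test.csv", index=False)
    log.info("stage=split train=%d test=%d", len(train), len(test))

    specs = model_grid()  # canonical family/region levels, reference Boidae/Africa
    if config.grid:
        specs = [s for s in specs if s.name in set(config.grid)]
        if not specs:
            raise RuntimeError("stage=fit: no grid members selected")

    fits = {}
    loos = []
    for spec in specs:
        try:
            design = build_design(train, spec)
            post = fit_grm(design, chains=config.chains, warmup=config.warmup,
                           draws=config.draws, seed=config.seed,
                           max_leapfrog=config.max_leapfrog)
        except Exception as e:
            raise RuntimeError(f"stage=fit model={spec.name}: {e}") from e
        fits[spec.name] = (design, post)
        post.save(out / f"posterior_{spec.name}")
        loos.append(psis_loo(post.log_lik, name=spec.name))
        log.info("stage=fit model=%s params=%d", spec.name, len(design.colnames))

    comparison = compare_models(loos)
    comparison.to_csv(out / "model_comparison.csv", index=False)
    best_name = comparison["model"].iloc[0]
    best_design, best_post = fits[best_name]
    log.info("stage=compare best=%s", best_name)

    diag = convergence_diagnostics(best_post)
    diag.to_csv(out / "convergence.csv", index=False)
    best_post.summary().to_csv(out / "posterior_summary.csv", index=False)

    test_design = build_design(test, best_design.spec, like=best_design)
    report = {
        "best_model": best_name,
        "mae_with_groups": heldout_mae(best_post, test_design, True),
        "mae_without_groups": heldout_mae(best_post, test_design, False),
        "r2_with_groups": float(np.median(bayes_r2(best_post, test_design, True))),
        "r2_without_groups": float(np.median(bayes_r2(best_post, test_design, False))),
    }
    log.info("stage=evaluate mae=%.3f/%.3f", report["mae_with_groups"],
             report["mae_without_groups"])

    quintiles = quintile_table(scored, min_photos=config.min_photos
                               if config.filter_min_photos else 1)
    quintiles.to_csv(out / "quintile_accuracy.csv", index=False)
    confusion = genus_confusion(scored, taxonomy)
    confusion.to_csv(out / "genus_confusion.csv", index=False)
    per_photo, consensus = photo_consensus_stats(scored)
    per_photo.to_csv(out / "photo_consensus.csv", index=False)
    report["consensus"] = consensus
    log.info("stage=summarize quintiles=%d confusion_rows=%d",
             len(quintiles), len(confusion))

    manifest = {"config": asdict(config), "config_hash": config.digest(),
                "seed": config.seed, "report": report}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
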