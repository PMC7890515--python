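"""Descriptive tables and model-derived summaries.

Participant quintile accuracies, per-genus confusion of medically important
snakes, per-photo consensus diagnostics, back-transformed predicted accuracy
grids, difficulty/discrimination rankings and the accuracy-vs-diversity
regression.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grm import GRMPosterior
from .taxonomy import Taxonomy, is_skip, normalize_name

_Z95 = 1.959963984540054


def _participant_accuracies(scored: pd.DataFrame) -> pd.DataFrame:
    g = scored.groupby("participant_id")
    out = pd.DataFrame({
        "n_responses": g.size(),
        "species_acc": g.apply(lambda d: (d["score"] == 3).mean(), include_groups=False),
        "genus_acc": g.apply(lambda d: (d["score"] >= 2).mean(), include_groups=False),
        "family_acc": g.apply(lambda d: (d["score"] >= 1).mean(), include_groups=False),
        "mivs_acc": g.apply(lambda d: d["mivs_correct"].mean(), include_groups=False),
    })
    return out


def quintile_table(scored: pd.DataFrame, min_photos: int = 80) -> pd.DataFrame:
    """Accuracy by participant quintile (percent, with 95% CI half-widths).

    Participants with at least ``min_photos`` responses are ranked by their
    species-level accuracy (ties broken by response count, then id) and cut
    into five equal groups.  Cell values are across-participant means of the
    per-participant accuracies; the CI is a normal approximation of the mean.
    A whole-community row is appended.
    """
    acc = _participant_accuracies(scored)
    acc = acc[acc["n_responses"] >= min_photos]
    if len(acc) < 5:
        raise ValueError(
            f"only {len(acc)} participants with >= {min_photos} responses; need >= 5")
    acc = acc.sort_values(
        ["species_acc", "n_responses", "participant_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    groups = np.array_split(np.arange(len(acc)), 5)
    labels = ["1st quintile (top 20%)", "2nd quintile", "3rd quintile",
              "4th quintile", "5th quintile (bottom 20%)"]

    def row(label, sub):
        out = {"group": label, "n_participants": len(sub)}
        for metric in ("species_acc", "genus_acc", "family_acc", "mivs_acc"):
            vals = sub[metric].to_numpy()
            out[metric] = 100.0 * vals.mean()
            out[metric + "_ci"] = (
                100.0 * _Z95 * vals.std(ddof=1) / np.sqrt(len(vals))
                if len(vals) > 1 else np.nan)
        return out

    rows = [row(lab, acc.iloc[idx]) for lab, idx in zip(labels, groups)]
    rows.append(row("Whole community", acc))
    return pd.DataFrame(rows)


def _answer_is_mivs(row, taxonomy: Taxonomy):
    """MIVS status of the answered taxon; None when no taxon was resolved."""
    if row.answer_rank == "species":
        return taxonomy.record(row.answer_binomen).is_mivs
    if row.answer_rank == "genus":
        return taxonomy.genus_is_mivs(row.answer_genus)
    if row.answer_rank == "family":
        return taxonomy.family_is_mivs(row.answer_family)
    return None


def genus_confusion(scored: pd.DataFrame, taxonomy: Taxonomy) -> pd.DataFrame:
    """Confusion summary per medically important genus.

    For each MIVS genus appearing as a true genus: response counts, percent
    correct at genus and species level, percent of responses identifying a
    non-MIVS taxon (reported against both all responses and non-skip
    responses — the stricter denominator choice is left to the reader), and
    the modal incorrect MIVS and non-MIVS genera with their shares of all
    responses.  Genera without responses are omitted.
    """
    df = scored.copy()
    df["true_genus"] = [taxonomy.record(s).genus for s in df["true_species"]]
    rows = []
    for genus in sorted(set(df["true_genus"])):
        if not taxonomy.genus_is_mivs(genus):
            continue
        sub = df[df["true_genus"] == genus]
        n = len(sub)
        answered_mivs = [
            _answer_is_mivs(r, taxonomy) for r in sub.itertuples(index=False)]
        non_mivs_answers = sum(1 for a in answered_mivs if a is False)
        n_nonskip = int((~sub["answer_raw"].map(is_skip)).sum())
        wrong = sub[(sub["answer_genus"].notna())
                    & (sub["answer_genus"] != genus)]
        wrong_mivs = wrong[[taxonomy.genus_is_mivs(g) for g in wrong["answer_genus"]]]
        wrong_non = wrong[[not taxonomy.genus_is_mivs(g) for g in wrong["answer_genus"]]]

        def modal(frame):
            if frame.empty:
                return None, 0.0
            counts = frame["answer_genus"].value_counts()
            return counts.index[0], 100.0 * counts.iloc[0] / n

        m_mivs, s_mivs = modal(wrong_mivs)
        m_non, s_non = modal(wrong_non)
        fam = taxonomy.species_in_genus(genus)[0].family
        rows.append({
            "family": fam,
            "genus": genus,
            "n_species": len(taxonomy.species_in_genus(genus)),
            "n_responses": n,
            "pct_genus_correct": 100.0 * (sub["answer_genus"] == genus).mean(),
            "pct_species_correct": 100.0 * (sub["score"] == 3).mean(),
            "pct_non_mivs_all": 100.0 * non_mivs_answers / n,
            "pct_non_mivs_nonskip": (
                100.0 * non_mivs_answers / n_nonskip if n_nonskip else np.nan),
            "modal_wrong_mivs_genus": m_mivs,
            "modal_wrong_mivs_pct": s_mivs,
            "modal_wrong_non_mivs_genus": m_non,
            "modal_wrong_non_mivs_pct": s_non,
        })
    return pd.DataFrame(rows)


def _answer_label(row):
    """Canonical label of a resolved answer for consensus counting."""
    if row.answer_rank == "species":
        return row.answer_binomen
    if row.answer_rank == "genus":
        return f"genus:{row.answer_genus}"
    if row.answer_rank == "family":
        return f"family:{row.answer_family}"
    if is_skip(row.answer_raw):
        return None
    return f"raw:{normalize_name(str(row.answer_raw))}"


def photo_consensus_stats(scored: pd.DataFrame):
    """Per-photo consensus diagnostics and their global summary.

    Returns ``(per_photo, summary)``.  ``per_photo`` has one row per photo:
    distinct resolved answers (skips excluded), the modal answer, whether the
    photo was majority-correct at species level (modal-answer ties count as
    incorrect — a conservative consensus), and the share of species-correct
    responses.  ``summary`` holds the majority-correct/incorrect photo counts
    and the Pearson correlation between answer diversity and correct share.
    """
    rows = []
    for photo_id, sub in scored.groupby("photo_id"):
        truth = sub["true_species"].iloc[0]
        labels = [_answer_label(r) for r in sub.itertuples(index=False)]
        named = [l for l in labels if l is not None]
        counts = pd.Series(named).value_counts() if named else pd.Series(dtype=int)
        if len(counts):
            modal = counts.index[0]
            tied = (counts == counts.iloc[0]).sum() > 1
            majority_correct = (modal == truth) and not tied
        else:
            modal, majority_correct = None, False
        rows.append({
            "photo_id": photo_id,
            "true_species": truth,
            "n_responses": len(sub),
            "unique_answers": len(counts),
            "modal_answer": modal,
            "majority_correct": bool(majority_correct),
            "correct_share": float((sub["score"] == 3).mean()),
        })
    per_photo = pd.DataFrame(rows)
    if per_photo["unique_answers"].nunique() > 1:
        corr = float(np.corrcoef(per_photo["unique_answers"],
                                 per_photo["correct_share"])[0, 1])
    else:
        corr = np.nan
    summary = {
        "n_photos": len(per_photo),
        "n_majority_correct": int(per_photo["majority_correct"].sum()),
        "n_majority_incorrect": int((~per_photo["majority_correct"]).sum()),
        "uniqueness_accuracy_correlation": corr,
    }
    return per_photo, summary


def consensus_share(n_agreeing: int, n_total: int) -> float:
    """Percentage of responses behind one answer (e.g. 57 of 79 -> 72%)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_agreeing / n_total


def predict_accuracy_grid(
    post: GRMPosterior,
    families: Sequence[str],
    regions: Sequence[str],
    home: Sequence[bool] = (False, True),
    taxa_repeats: Sequence[int] = (0,),
) -> pd.DataFrame:
    """Posterior predicted accuracy for a family x region x home x repeat grid.

    Per cell: median and 95% credible interval of P(score >= 1) (family
    level), P(score >= 2) (genus level) and P(score = 3) (species level),
    with all group deviations at 0 (an average participant, photo and
    species).
    """
    spec = post.spec
    cols = post.colnames
    pos = {c: i for i, c in enumerate(cols)}
    beta = post.stacked("beta")
    tau = post.stacked("tau")
    delta0 = post.stacked("delta0") if "delta0" in post.draws else np.zeros(len(beta))
    alpha = np.exp(delta0)

    for f in families:
        if f != spec.families[0] and f not in pos:
            raise ValueError(f"family {f!r} not in design")
    for r in regions:
        if r != spec.regions[0] and r not in pos:
            raise ValueError(f"region {r!r} not in design")

    rows = []
    from scipy.special import expit
    for f in families:
        for r in regions:
            for h in home:
                for t in taxa_repeats:
                    x = np.zeros(len(cols))
                    if f in pos:
                        x[pos[f]] = 1.0
                    if r in pos:
                        x[pos[r]] = 1.0
                    if h:
                        if "home_region = T" not in pos:
                            raise ValueError("home effect not in design")
                        x[pos["home_region = T"]] = 1.0
                        inter = f"{r}: home_region = T"
                        if inter in pos:
                            x[pos[inter]] = 1.0
                    x[pos["taxa_repeat"]] = float(t)
                    eta = beta @ x
                    cum = expit(alpha[:, None] * (tau - eta[:, None]))
                    probs = {
                        "family": 1.0 - cum[:, 0],   # P(score >= 1)
                        "genus": 1.0 - cum[:, 1],    # P(score >= 2)
                        "species": 1.0 - cum[:, 2],  # P(score = 3)
                    }
                    for level, p in probs.items():
                        q = np.quantile(p, [0.5, 0.025, 0.975])
                        rows.append({
                            "family": f, "region": r, "home": h,
                            "taxa_repeat": t, "level": level,
                            "median": q[0], "l95": q[1], "u95": q[2],
                        })
    return pd.DataFrame(rows)


def difficulty_discrimination_report(post: GRMPosterior) -> dict:
    """Ranked species/photo effects and latent-scale comparisons.

    Species and photos are ranked most-difficult first (difficulty is the
    negated location deviation: lower b pushes scores down).  Also reports
    the participant:species and participant:photo sd ratios (participant sd
    is fixed at 1) and posterior summaries of the difficulty-discrimination
    correlations.
    """
    out = {}
    for prefix, ids in (("species", post.species_ids), ("photo", post.photo_ids)):
        b = np.median(post.stacked(f"{prefix}_b"), axis=0)
        d = np.median(post.stacked(f"{prefix}_d"), axis=0)
        df = pd.DataFrame({prefix: ids, "difficulty": -b, "discrimination_dev": d})
        out[f"{prefix}_effects"] = df.sort_values(
            "difficulty", ascending=False, kind="mergesort").reset_index(drop=True)
    sd_sp = float(np.median(post.stacked("sd_species_b")))
    sd_ph = float(np.median(post.stacked("sd_photo_b")))
    out["sd_ratio_participant_species"] = 1.0 / sd_sp
    out["sd_ratio_participant_photo"] = 1.0 / sd_ph
    for name in ("cor_photo", "cor_species"):
        s = post.stacked(name)
        q = np.quantile(s, [0.5, 0.025, 0.975])
        out[name] = {"median": float(q[0]), "l95": float(q[1]), "u95": float(q[2])}
    return out


def variance_scale_ratios(sd_participant: float, sd_species: float,
                          sd_photo: float) -> dict:
    """Participant:species and participant:photo difficulty-sd ratios."""
    return {
        "participant_species": sd_participant / sd_species,
        "participant_photo": sd_participant / sd_photo,
    }


def taxon_accuracy_table(scored: pd.DataFrame, taxonomy: Taxonomy,
                         level: str = "genus") -> pd.DataFrame:
    """Species-level accuracy and species richness per genus or family."""
    if level not in ("genus", "family"):
        raise ValueError("level must be 'genus' or 'family'")
    df = scored.copy()
    if level == "genus":
        df["taxon"] = [taxonomy.record(s).genus for s in df["true_species"]]
        richness = {g: len(taxonomy.species_in_genus(g))
                    for g in df["taxon"].unique()}
    else:
        df["taxon"] = [taxonomy.record(s).family for s in df["true_species"]]
        richness = {f: sum(1 for r in taxonomy.records if r.family == f)
                    for f in df["taxon"].unique()}
    acc = df.groupby("taxon").apply(
        lambda d: (d["score"] == 3).mean(), include_groups=False)
    return pd.DataFrame({
        "taxon": acc.index,
        "accuracy": acc.to_numpy(),
        "richness": [richness[t] for t in acc.index],
    }).reset_index(drop=True)


def diversity_regression(table: pd.DataFrame) -> dict:
    """OLS of identification accuracy on species richness.

    Reports the slope and *adjusted* R² (negative values possible when the
    predictor explains less than one parameter's worth of variance).
    """
    import statsmodels.api as sm

    if len(table) < 3:
        raise ValueError("need at least 3 taxa")
    x = table["richness"].to_numpy(dtype=float)
    y = table["accuracy"].to_numpy(dtype=float)
    if np.all(x == x[0]):
        return {"slope": np.nan, "intercept": np.nan, "r2_adj": np.nan,
                "degenerate": True}
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {"slope": float(model.params[1]), "intercept": float(model.params[0]),
            "r2_adj": float(model.rsquared_adj), "degenerate": False}
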