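"""Seeded experiment drivers over the simulator and the SHscore.

Each driver simulates a controlled heterogeneity scenario, scores it, and
returns an :class:`ExperimentReport` whose summary statistics are
recomputable from the stored per-replicate table.  Default problem sizes
are a desk profile (1000-leaf trees on the reduced one-chromosome genome);
every driver takes explicit sizes for larger runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cnvdata import CNVMatrix, aggregate
from .het import pairwise_distance, shscore_from_distances, shscore
from .sim import (Genome, SimulationConfig, reduced_genome, scenario_het,
                  scenario_hom, scenario_metastasis, scenario_var,
                  simulate_tree, subtree_samples)


@dataclass
class ExperimentReport:
    """Scenario name, per-replicate scores, summaries and test statistics."""

    scenario: str
    table: pd.DataFrame
    summary: dict
    stats: dict
    config: dict
    seed: int | None

    def group_scores(self, group: str) -> np.ndarray:
        t = self.table
        return t.loc[t["group"] == group, "score"].to_numpy()


def summarize(values) -> dict:
    """min / max / median / IQR of a score vector."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    return {"n": int(v.size), "min": float(v.min()), "max": float(v.max()),
            "median": float(np.median(v)), "iqr": float(q3 - q1)}


def _mannwhitney(x, y) -> dict:
    """Two-sided Mann-Whitney U (exact for small groups, else asymptotic)."""
    x, y = np.asarray(x), np.asarray(y)
    method = "exact" if max(len(x), len(y)) <= 20 else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:  # ties make the exact method unavailable
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
    return {"U": float(res.statistic), "p_value": float(res.pvalue),
            "method": method}


def _pearson(x, y) -> dict:
    res = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return {"r": float(res.statistic), "p_value": float(res.pvalue)}


def _child_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def _two_sample_score(sample_a: CNVMatrix, sample_b: CNVMatrix) -> float:
    pooled = aggregate([sample_a, sample_b], ["A", "B"])
    return shscore(pooled).score


# ---------------------------------------------------------------------------
# regional subsampling: segregation (hom) vs intermixing (het)
# ---------------------------------------------------------------------------

def run_regional(replicates: int = 20, n_leaves: int = 1000, k: int = 5,
                 seed: int | None = 0, genome: Genome | None = None,
                 **config_kwargs) -> ExperimentReport:
    """Score founder-progeny vs shuffled groupings on the same trees.

    Per replicate one tree is simulated and scored twice on one distance
    matrix: once with the progeny of the first ``k`` generated cells as
    subsamples (*hom*, spatial segregation) and once with leaves assigned
    to ``k`` subsamples at random (*het*, spatial intermixing).  The two
    score distributions are compared with a two-sided Mann-Whitney U test.
    """
    if genome is None:
        genome = reduced_genome()
    rows = []
    for rep, ss in enumerate(_child_seeds(seed, replicates)):
        rng_tree, rng_het = map(np.random.default_rng, ss.spawn(2))
        config = SimulationConfig(n_leaves=n_leaves, genome=genome,
                                  **config_kwargs)
        tree = simulate_tree(config, rng=rng_tree)
        matrix = tree.leaves_to_matrix()
        D = pairwise_distance(matrix)
        hom = shscore_from_distances(D, scenario_hom(tree, k))
        het = shscore_from_distances(D, scenario_het(tree, k, rng=rng_het))
        rows.append({"replicate": rep, "group": "hom", "score": hom})
        rows.append({"replicate": rep, "group": "het", "score": het})
    table = pd.DataFrame(rows)
    hom_scores = table.loc[table.group == "hom", "score"]
    het_scores = table.loc[table.group == "het", "score"]
    return ExperimentReport(
        scenario="regional",
        table=table,
        summary={"hom": summarize(hom_scores), "het": summarize(het_scores)},
        stats={"mannwhitney": _mannwhitney(hom_scores, het_scores)},
        config={"replicates": replicates, "n_leaves": n_leaves, "k": k,
                **config_kwargs},
        seed=seed)


# ---------------------------------------------------------------------------
# metastasis seeding
# ---------------------------------------------------------------------------

def run_metastasis(replicates: int = 20, n_leaves_each: int = 500,
                   seed: int | None = 0, genome: Genome | None = None,
                   early_fraction: float = 0.25, late_fraction: float = 0.75,
                   **config_kwargs) -> ExperimentReport:
    """Primary/metastasis pairs seeded early vs late in primary growth."""
    if genome is None:
        genome = reduced_genome()
    rows = []
    seeds = _child_seeds(seed, 2 * replicates)
    for rep in range(replicates):
        for group, frac, ss in (("early", early_fraction, seeds[2 * rep]),
                                ("late", late_fraction, seeds[2 * rep + 1])):
            config = SimulationConfig(n_leaves=n_leaves_each, genome=genome,
                                      **config_kwargs)
            prim, met = scenario_metastasis(
                config, seed_fraction=frac, n_leaves_each=n_leaves_each,
                seed=int(ss.generate_state(1)[0] % (2**31)))
            pooled = aggregate([prim, met], ["primary", "metastasis"])
            rows.append({"replicate": rep, "group": group,
                         "score": shscore(pooled).score})
    table = pd.DataFrame(rows)
    early = table.loc[table.group == "early", "score"]
    late = table.loc[table.group == "late", "score"]
    return ExperimentReport(
        scenario="metastasis",
        table=table,
        summary={"early": summarize(early), "late": summarize(late)},
        stats={"mannwhitney": _mannwhitney(early, late)},
        config={"replicates": replicates, "n_leaves_each": n_leaves_each,
                "early_fraction": early_fraction,
                "late_fraction": late_fraction, **config_kwargs},
        seed=seed)


# ---------------------------------------------------------------------------
# parameter independence
# ---------------------------------------------------------------------------

def run_var(replicates: int = 100, n_leaves: int = 1000,
            seed: int | None = 0, genome: Genome | None = None,
            **config_kwargs) -> ExperimentReport:
    """SHscore vs the event-size and copy-gain parameters.

    Each replicate draws ``theta ~ U[500, 5e6]`` and ``gain_p ~ U[0.1,
    0.9]``, simulates one tree split at the root into two samples, and
    scores the pair; Pearson correlations of the score against both drawn
    parameters quantify (in)dependence.
    """
    if genome is None:
        genome = reduced_genome()
    rows = []
    for rep, ss in enumerate(_child_seeds(seed, replicates)):
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        sample_a, sample_b, theta, gain_p = scenario_var(
            seed=rep_seed, n_leaves=n_leaves, genome=genome, **config_kwargs)
        rows.append({"replicate": rep, "group": "var", "theta": theta,
                     "gain_p": gain_p,
                     "score": _two_sample_score(sample_a, sample_b)})
    table = pd.DataFrame(rows)
    return ExperimentReport(
        scenario="var",
        table=table,
        summary={"var": summarize(table["score"])},
        stats={"pearson_theta": _pearson(table["theta"], table["score"]),
               "pearson_gain_p": _pearson(table["gain_p"], table["score"])},
        config={"replicates": replicates, "n_leaves": n_leaves,
                **config_kwargs},
        seed=seed)


# ---------------------------------------------------------------------------
# evolutionary (MRCA) distance
# ---------------------------------------------------------------------------

def run_deep(total_leaves: int = 10_000, first_k: int = 20,
             n_pairs_scored: int | None = None, seed: int | None = 0,
             genome: Genome | None = None, iqr_filter: bool = True,
             **config_kwargs) -> ExperimentReport:
    """Pairwise SHscores vs MRCA distance on one deep tree.

    One tree of ``total_leaves`` leaves is grown; the subtrees rooted in
    the first ``first_k`` generated cells become samples (IQR-balanced by
    default).  Every retained sample pair (or a random subset of
    ``n_pairs_scored``) is scored, and the score is correlated with the
    edge distance between the founder cells on the parental tree.
    """
    if genome is None:
        genome = reduced_genome()
    ss = np.random.SeedSequence(seed)
    rng_tree, rng_pairs = map(np.random.default_rng, ss.spawn(2))
    config = SimulationConfig(n_leaves=total_leaves, genome=genome,
                              **config_kwargs)
    tree = simulate_tree(config, rng=rng_tree)
    samples = subtree_samples(tree, first_k, iqr_filter=iqr_filter)
    pairs = list(combinations(range(len(samples)), 2))
    if n_pairs_scored is not None and n_pairs_scored < len(pairs):
        idx = rng_pairs.choice(len(pairs), size=n_pairs_scored, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    rows = []
    for i, j in pairs:
        (mat_i, root_i), (mat_j, root_j) = samples[i], samples[j]
        rows.append({"pair": f"F{root_i}-F{root_j}", "group": "deep",
                     "score": _two_sample_score(mat_i, mat_j),
                     "mrca_distance": tree.mrca_distance(root_i, root_j)})
    table = pd.DataFrame(rows)
    return ExperimentReport(
        scenario="deep",
        table=table,
        summary={"deep": summarize(table["score"])},
        stats={"pearson_mrca": _pearson(table["mrca_distance"],
                                        table["score"]),
               "n_samples_retained": len(samples)},
        config={"total_leaves": total_leaves, "first_k": first_k,
                "n_pairs_scored": n_pairs_scored, "iqr_filter": iqr_filter,
                **config_kwargs},
        seed=seed)


def run_depth_sweep(settings=((250, 5, 6), (1000, 20, 3), (4000, 80, 1)),
                    pairs_per_tree: int = 45, seed: int | None = 0,
                    genome: Genome | None = None,
                    **config_kwargs) -> ExperimentReport:
    """Median pairwise SHscore across founder-depth settings.

    Each setting is ``(n_leaves, first_k, n_trees)`` with a constant
    leaves-per-founder ratio, so sample cardinality is comparable while
    the founders sit at increasing depth on ever larger trees -- deeper
    founders mean more divergent sample ancestors and higher scores.
    Pairwise scores are pooled over the setting's trees (at most
    ``pairs_per_tree`` random pairs each).
    """
    if genome is None:
        genome = reduced_genome()
    rows = []
    ss = np.random.SeedSequence(seed)
    for (n_leaves, first_k, n_trees) in settings:
        for t, child in enumerate(ss.spawn(n_trees)):
            rng_tree, rng_pairs = map(np.random.default_rng, child.spawn(2))
            config = SimulationConfig(n_leaves=n_leaves, genome=genome,
                                      **config_kwargs)
            tree = simulate_tree(config, rng=rng_tree)
            samples = subtree_samples(tree, first_k, iqr_filter=True)
            pairs = list(combinations(range(len(samples)), 2))
            if len(pairs) > pairs_per_tree:
                idx = rng_pairs.choice(len(pairs), size=pairs_per_tree,
                                       replace=False)
                pairs = [pairs[i] for i in sorted(idx)]
            for i, j in pairs:
                (mat_i, _), (mat_j, _) = samples[i], samples[j]
                rows.append({"group": f"L{n_leaves}_k{first_k}", "tree": t,
                             "n_leaves": n_leaves, "first_k": first_k,
                             "score": _two_sample_score(mat_i, mat_j)})
    table = pd.DataFrame(rows)
    summary = {g: summarize(sub["score"])
               for g, sub in table.groupby("group", sort=False)}
    medians = [summary[f"L{n}_k{k}"]["median"] for (n, k, _) in settings]
    return ExperimentReport(
        scenario="depth_sweep",
        table=table,
        summary=summary,
        stats={"medians_by_depth": medians,
               "strictly_increasing": bool(np.all(np.diff(medians) > 0))},
        config={"settings": [tuple(s) for s in settings],
                "pairs_per_tree": pairs_per_tree, **config_kwargs},
        seed=seed)


# ---------------------------------------------------------------------------
# downsampling robustness
# ---------------------------------------------------------------------------

def run_downsampling(sample_a: CNVMatrix, sample_b: CNVMatrix,
                     fractions=(1.0, 0.75, 0.5, 0.25), draws: int = 10,
                     seed: int | None = 0) -> ExperimentReport:
    """SHscore stability when one sample is randomly downsampled.

    For each fraction, ``sample_b`` is subsampled without replacement
    ``draws`` times and the two-sample SHscore recomputed; dispersion
    across draws measures robustness to unbalanced cell counts.
    Fraction 1.0 reproduces the full-data score exactly.
    """
    rng = np.random.default_rng(seed)
    full = _two_sample_score(sample_a, sample_b)
    rows = []
    for frac in fractions:
        n_keep = max(2, int(round(frac * sample_b.n_cells)))
        for d in range(draws):
            if n_keep >= sample_b.n_cells:
                sub = sample_b
            else:
                idx = np.sort(rng.choice(sample_b.n_cells, size=n_keep,
                                         replace=False))
                sub = sample_b.subset_cells(idx)
            rows.append({"group": f"f{frac:g}", "fraction": frac, "draw": d,
                         "score": _two_sample_score(sample_a, sub)})
    table = pd.DataFrame(rows)
    summary = {g: summarize(sub["score"])
               for g, sub in table.groupby("group", sort=False)}
    return ExperimentReport(
        scenario="downsampling",
        table=table,
        summary=summary,
        stats={"full_score": full},
        config={"fractions": list(fractions), "draws": draws},
        seed=seed)
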