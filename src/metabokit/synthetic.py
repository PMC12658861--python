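"""Synthetic omics data with planted structure.

These generators emulate the statistical shape of a two-group case/control
omics study with covariates (age and ancestry): log-scale Gaussian feature
abundances, a subset of features carrying a planted between-group shift,
sprinkled missing/zero cells, and pathway collections in which exactly one
pathway's members carry the planted effects. They exist so the association,
multivariate and pathway modules are testable end-to-end with known truth;
everything is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_table import FeatureTable
from .iopa import OmicsSummary, PathwayGraph

__all__ = ["SimulationSpec", "simulate_feature_table", "simulate_pathways"]


@dataclass
class SimulationSpec:
    """Study-condition parameters for the generators.

    Defaults model a moderate two-group metabolomics study: 30 samples per
    group, 200 features of which 20 carry a delta = 2 sd group shift, unit
    log-scale noise, a mild age effect, and 2% missing / 2% zero cells.
    """

    n_per_group: int = 30
    n_features: int = 200
    n_planted: int = 20
    delta: float = 2.0              # planted group shift, in noise-sd units
    noise_sd: float = 1.0
    covariate_effect: float = 0.5   # per-sd-of-age effect on every feature
    missing_rate: float = 0.02
    zero_rate: float = 0.02
    # pathway generator
    n_pathways: int = 20
    genes_per_pathway: int = 10
    compounds_per_pathway: int = 3
    edges_per_pathway: int = 12
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_group, self.n_features, self.n_pathways) < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")


def simulate_feature_table(spec: SimulationSpec):
    """Two-group log-scale abundance matrix with planted effects.

    Returns ``(table, truth)``: a :class:`FeatureTable` whose metadata has
    ``group`` (case/control), ``age`` and ``ancestry`` columns, and a truth
    dict with the planted feature ids and the generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_group
    groups = np.array(["control"] * spec.n_per_group + ["case"] * spec.n_per_group)
    age = rng.normal(0.0, 1.0, size=n)
    ancestry = rng.integers(0, 2, size=n).astype(float)
    sample_ids = [f"S{i:03d}" for i in range(n)]
    feature_ids = [f"F{j:04d}" for j in range(spec.n_features)]
    planted = feature_ids[: spec.n_planted]

    base = rng.normal(10.0, 1.0, size=spec.n_features)
    X = (base[:, None]
         + rng.normal(0.0, spec.noise_sd, size=(spec.n_features, n)))
    X += spec.covariate_effect * age[None, :]
    shift = spec.delta * spec.noise_sd
    X[: spec.n_planted, groups == "case"] += shift

    # sprinkle NA then zeros on distinct cells
    total = spec.n_features * n
    flat = rng.permutation(total)
    n_na = int(round(spec.missing_rate * total))
    n_zero = int(round(spec.zero_rate * total))
    Xf = X.ravel()
    Xf[flat[:n_na]] = np.nan
    Xf[flat[n_na:n_na + n_zero]] = 0.0
    X = Xf.reshape(spec.n_features, n)

    values = pd.DataFrame(X, index=feature_ids, columns=sample_ids)
    meta = pd.DataFrame({"group": groups, "age": age, "ancestry": ancestry},
                        index=sample_ids)
    truth = {"planted": planted, "delta": shift, "spec": spec}
    return FeatureTable(values, meta), truth


def _random_graph(rng, pid: str, name: str, genes: list[str],
                  compounds: list[str], n_edges: int) -> PathwayGraph:
    nodes = {(g, "gene") for g in genes} | {(c, "compound") for c in compounds}
    ids = genes + compounds
    edges = set()
    for _ in range(n_edges):
        src, dst = rng.choice(len(ids), size=2, replace=False)
        sign = int(rng.choice([1, -1]))
        edges.add((ids[src], ids[dst], sign,
                   "activation" if sign > 0 else "inhibition"))
    return PathwayGraph(pid, name, nodes, edges)


def simulate_pathways(spec: SimulationSpec):
    """Pathway collection plus gene/compound summary statistics with one
    enriched pathway.

    Every feature appears in the summaries (the ORA universe). Members of
    pathway ``PW000`` carry large effects with tiny p-values; all other
    features are null (beta ~ N(0, 0.1), p ~ U(0,1)). Returns
    ``(pathways, gene_summary, compound_summary, truth)``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    pathways = []
    all_genes, all_compounds = [], []
    for i in range(spec.n_pathways):
        genes = [f"G{i:03d}_{j}" for j in range(spec.genes_per_pathway)]
        comps = [f"C{i:03d}_{j}" for j in range(spec.compounds_per_pathway)]
        all_genes.extend(genes)
        all_compounds.extend(comps)
        pathways.append(_random_graph(rng, f"PW{i:03d}", f"pathway {i}",
                                      genes, comps, spec.edges_per_pathway))
    enriched = pathways[0]
    enriched_ids = enriched.members()

    def _summary(ids, kind):
        rows = []
        for fid in ids:
            if fid in enriched_ids:
                beta = float(rng.normal(spec.delta, 0.2) * rng.choice([1, -1]))
                p = float(10 ** rng.uniform(-8, -4))
            else:
                beta = float(rng.normal(0.0, 0.1))
                p = float(rng.uniform())
            rows.append((fid, kind, beta, p))
        df = pd.DataFrame(rows, columns=["feature_id", "kind", "beta", "p"])
        df["significant"] = (np.abs(df["beta"]) > spec.delta / 2) & (df["p"] < 0.05)
        return OmicsSummary(df)

    gene_summary = _summary(all_genes, "gene")
    compound_summary = _summary(all_compounds, "compound")
    truth = {"enriched": enriched.pathway_id, "spec": spec}
    return pathways, gene_summary, compound_summary, truth
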