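"""Integrative omics pathway analysis: joint gene + compound
over-representation, topology-aware perturbation (an extension of signaling
pathway impact analysis to mixed gene/compound graphs), p-value combination
and multiplicity control.

A pathway is a typed directed graph: gene and compound nodes, signed edges
(activation +1, inhibition -1). Per-feature summary statistics (effect size
beta and p-value) from upstream association analysis feed two complementary
tests per pathway:

* ORA — hypergeometric upper tail on the count of significant members;
  run per omic (gene, compound) and jointly on the pooled universe.
* eSPIA — the net accumulated perturbation t_A from propagating observed
  effect sizes through the signed topology, with a bootstrap null that
  reassigns the observed effects to random pathway nodes (median-corrected
  tail probability, the SPIA convention).

The two p-values are combined by Fisher's method or a permutation-based
dependence-aware combiner, then adjusted across pathways (BH / Bonferroni).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PathwayGraph",
    "OmicsSummary",
    "PathwayResult",
    "load_pathways",
    "load_pathways_tsv",
    "load_pathways_kgml",
    "ora",
    "espia",
    "combine_p",
    "adjust_p",
    "iopa_run",
]

_SIGN = {"activation": 1, "expression": 1, "+1": 1, "1": 1, "+": 1,
         "inhibition": -1, "repression": -1, "-1": -1, "-": -1}


@dataclass
class PathwayGraph:
    pathway_id: str
    name: str
    nodes: set = field(default_factory=set)       # {(node_id, kind)}
    edges: set = field(default_factory=set)       # {(src, dst, sign, label)}
    category: str = ""                            # KEGG map category, if known

    def __post_init__(self):
        ids = {nid for nid, _ in self.nodes}
        for src, dst, sign, _ in self.edges:
            if src not in ids or dst not in ids:
                raise ValueError(
                    f"pathway {self.pathway_id}: edge {src}->{dst} has a "
                    f"dangling endpoint")
            if sign not in (1, -1):
                raise ValueError(f"edge sign must be +/-1, got {sign}")

    def members(self, kind: str | None = None) -> set[str]:
        return {nid for nid, k in self.nodes if kind is None or k == kind}


@dataclass
class OmicsSummary:
    """Per-feature summary statistics table.

    ``table`` columns: feature_id, kind ('gene'/'compound'), beta, p,
    significant (bool).
    """

    table: pd.DataFrame

    @classmethod
    def from_stats(cls, df: pd.DataFrame, kind: str,
                   beta_threshold: float | None = None,
                   p_fdr_max: float | None = None) -> "OmicsSummary":
        """Build from an association table with feature_id index and columns
        beta, p (and p_fdr if the FDR rule is used). Exactly one of
        ``beta_threshold`` (|beta| > thr) or ``p_fdr_max`` decides
        significance."""
        out = pd.DataFrame({
            "feature_id": df.index.astype(str),
            "kind": kind,
            "beta": df["beta"].to_numpy(dtype=float),
            "p": df["p"].to_numpy(dtype=float),
        })
        if (beta_threshold is None) == (p_fdr_max is None):
            raise ValueError("choose exactly one significance rule")
        if beta_threshold is not None:
            out["significant"] = np.abs(out["beta"]) > beta_threshold
        else:
            out["significant"] = df["p_fdr"].to_numpy(dtype=float) < p_fdr_max
        return cls(out)

    def ids(self, kind: str | None = None) -> set[str]:
        t = self.table
        if kind is not None:
            t = t[t["kind"] == kind]
        return set(t["feature_id"])

    def significant_ids(self, kind: str | None = None) -> set[str]:
        t = self.table[self.table["significant"]]
        if kind is not None:
            t = t[t["kind"] == kind]
        return set(t["feature_id"])

    def beta_of(self) -> dict[str, float]:
        return dict(zip(self.table["feature_id"], self.table["beta"]))


# --------------------------------------------------------------------------
# pathway loading
# --------------------------------------------------------------------------

def load_pathways_tsv(nodes_path, edges_path, sep: str = "\t"):
    """Load pathways from the node/edge TSV dialect.

    nodes file columns: pathway_id, pathway_name, node_id, kind
    edges file columns: pathway_id, src, dst, relation  (relation is an
    activation/inhibition label or a +/-1 literal; unsigned relations are
    dropped and counted)
    """
    ndf = pd.read_csv(nodes_path, sep=sep, dtype=str)
    edf = pd.read_csv(edges_path, sep=sep, dtype=str) if edges_path else None
    graphs: dict[str, PathwayGraph] = {}
    for i, row in ndf.iterrows():
        if row.isna().any():
            raise ValueError(f"{nodes_path}: malformed node row at line {i + 2}")
        pid = row["pathway_id"]
        g = graphs.setdefault(pid, PathwayGraph(pid, row["pathway_name"]))
        if row["kind"] not in ("gene", "compound"):
            raise ValueError(
                f"{nodes_path} line {i + 2}: kind must be gene or compound")
        g.nodes.add((row["node_id"], row["kind"]))
    dropped = 0
    if edf is not None:
        for i, row in edf.iterrows():
            pid = row["pathway_id"]
            if pid not in graphs:
                raise ValueError(
                    f"{edges_path} line {i + 2}: unknown pathway {pid}")
            sign = _SIGN.get(str(row["relation"]).strip().lower())
            if sign is None:
                dropped += 1
                continue
            g = graphs[pid]
            ids = {nid for nid, _ in g.nodes}
            if row["src"] not in ids or row["dst"] not in ids:
                raise ValueError(
                    f"{edges_path} line {i + 2}: dangling edge endpoint")
            g.edges.add((row["src"], row["dst"], sign, str(row["relation"])))
    out = []
    for g in graphs.values():
        out.append(PathwayGraph(g.pathway_id, g.name, g.nodes, g.edges,
                                g.category))
    if dropped:
        warnings.warn(f"dropped {dropped} unsigned relations")
    return out


def load_pathways_kgml(paths):
    """Parse KGML (KEGG XML) files into pathway graphs.

    Entry types 'gene' and 'compound' become nodes (KEGG names may list
    several ids per entry; each becomes a node). Relations with an
    activation/expression subtype get sign +1, inhibition/repression -1;
    other relations are dropped with a count.
    """
    graphs = []
    dropped = 0
    for path in paths:
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as exc:
            raise ValueError(f"{path}: malformed KGML ({exc})") from exc
        root = tree.getroot()
        pid = root.get("name", "").replace("path:", "") or root.get("number", "?")
        g = PathwayGraph(pid, root.get("title", pid))
        entry_ids: dict[str, list[tuple[str, str]]] = {}
        for entry in root.findall("entry"):
            etype = entry.get("type")
            if etype not in ("gene", "compound"):
                continue
            members = []
            for name in entry.get("name", "").split():
                nid = name.split(":", 1)[-1]
                members.append((nid, etype))
                g.nodes.add((nid, etype))
            entry_ids[entry.get("id")] = members
        for rel in root.findall("relation"):
            sign = None
            label = ""
            for sub in rel.findall("subtype"):
                label = sub.get("name", "")
                sign = _SIGN.get(label.lower(), sign)
            if sign is None:
                dropped += 1
                continue
            for src, _ in entry_ids.get(rel.get("entry1"), []):
                for dst, _ in entry_ids.get(rel.get("entry2"), []):
                    g.edges.add((src, dst, sign, label))
        graphs.append(PathwayGraph(g.pathway_id, g.name, g.nodes, g.edges))
    if dropped:
        warnings.warn(f"dropped {dropped} unsigned relations")
    return graphs


def load_pathways(source, edges=None):
    """Dispatch: a list of .xml paths goes to the KGML parser; otherwise
    ``source``/``edges`` are the node/edge TSV pair."""
    if isinstance(source, (list, tuple)):
        return load_pathways_kgml(source)
    if str(source).endswith((".xml", ".kgml")):
        return load_pathways_kgml([source])
    return load_pathways_tsv(source, edges)


# --------------------------------------------------------------------------
# tests
# --------------------------------------------------------------------------

def ora(pathway: PathwayGraph, summary: OmicsSummary, mode: str = "joint"):
    """Hypergeometric over-representation test.

    mode 'gene'/'compound' restricts the universe to that omic; 'joint'
    pools both. Returns ``(p, counts)`` with counts = dict(N, K, n, k).
    p = P(X >= k) for X ~ Hypergeom(N, K, n); an empty pathway-in-universe
    set gives p = 1 with n = 0.
    """
    kind = None if mode == "joint" else mode
    universe = summary.ids(kind)
    if not universe:
        raise ValueError(f"empty universe for mode {mode!r}")
    sig = summary.significant_ids(kind)
    members = pathway.members(kind) & universe
    N, K, n = len(universe), len(sig), len(members)
    k = len(members & sig)
    counts = {"N": N, "K": K, "n": n, "k": k}
    if n == 0:
        return 1.0, counts
    p = float(_sps.hypergeom.sf(k - 1, N, K, n))
    return min(1.0, p), counts


def _propagation_matrix(pathway: PathwayGraph, order: list[str]) -> np.ndarray:
    idx = {nid: i for i, nid in enumerate(order)}
    outdeg = {nid: 0 for nid in order}
    for src, _dst, _s, _l in pathway.edges:
        outdeg[src] += 1
    B = np.zeros((len(order), len(order)))
    for src, dst, sign, _ in pathway.edges:
        B[idx[dst], idx[src]] += sign / outdeg[src]
    return B


def espia(pathway: PathwayGraph, delta_e: dict[str, float],
          n_boot: int = 1000, seed: int = 0, damping: float = 0.99):
    """Topology perturbation test on the joint gene+compound graph.

    Solves PF = dE + B PF where B[v,u] = sign(u,v)/outdeg(u), accumulation
    Acc = PF - dE, and the statistic t_A = sum(Acc). The null reassigns the
    multiset of observed nonzero effects to uniformly random pathway nodes;
    the two-sided p-value is the median-corrected bootstrap tail. A singular
    system (cyclic gain >= 1) is damped with a warning.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    order = sorted(pathway.members())
    if not order:
        raise ValueError(f"pathway {pathway.pathway_id} is empty")
    nn = len(order)
    B = _propagation_matrix(pathway, order)
    A = np.eye(nn) - B
    if abs(np.linalg.det(A)) < 1e-12:
        warnings.warn(f"pathway {pathway.pathway_id}: singular propagation "
                      f"system; damping by {damping}")
        A = np.eye(nn) - damping * B
    solve = np.linalg.inv(A)

    def t_a(de_vec: np.ndarray) -> float:
        pf = solve @ de_vec
        return float((pf - de_vec).sum())

    de = np.array([delta_e.get(nid, 0.0) for nid in order])
    t_obs = t_a(de)
    effects = de[de != 0]
    if effects.size == 0:
        return t_obs, 1.0
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    for b in range(n_boot):
        vec = np.zeros(nn)
        pos = rng.choice(nn, size=min(effects.size, nn), replace=False)
        vec[pos] = rng.permutation(effects)[: len(pos)]
        null[b] = t_a(vec)
    med = float(np.median(null))
    p = (np.sum(np.abs(null - med) >= abs(t_obs - med)) + 1) / (n_boot + 1)
    return t_obs, float(min(1.0, p))


def combine_p(p1: float, p2: float, method: str = "fisher",
              null_pairs: np.ndarray | None = None) -> float:
    """Combine two p-values.

    'fisher': X = -2(ln p1 + ln p2) against chi-square(4). 'pbine': a
    dependence-aware empirical combination — the tail of Fisher's statistic
    under a supplied joint null sample ``null_pairs`` (k x 2 array of null
    (p1, p2) pairs, e.g. from permuting significance labels). This is an
    approximation built for this package, not the original Pbine algorithm.
    """
    tiny = np.finfo(float).tiny
    ps = []
    for p in (p1, p2):
        if p <= 0:
            warnings.warn("p <= 0 clamped to smallest positive float")
            p = tiny
        if p > 1:
            raise ValueError(f"p-value {p} > 1")
        ps.append(p)
    x = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    if method == "fisher":
        return float(_sps.chi2.sf(x, df=4))
    if method == "pbine":
        if null_pairs is None:
            raise ValueError("pbine requires null_pairs")
        arr = np.clip(np.asarray(null_pairs, dtype=float), tiny, 1.0)
        null_x = -2.0 * np.log(arr).sum(axis=1)
        return float((np.sum(null_x >= x) + 1) / (len(null_x) + 1))
    raise ValueError(f"unknown method {method!r}")


def adjust_p(pvec, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjustment."""
    arr = np.asarray(pvec, dtype=float)
    if method == "fdr_bh":
        return multipletests(arr, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(1.0, arr * arr.size)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class PathwayResult:
    pathway_id: str
    name: str
    G_n: int; deG_n: int; C_n: int; deC_n: int; P_n: int; deP_n: int
    p_ora_gene: float; p_ora_compound: float; p_ora_joint: float
    t_A: float; p_espia: float
    p_combined: float
    p_fdr: float = np.nan
    p_bonferroni: float = np.nan
    espia_score: float = np.nan  # normalized perturbation, in [-1, 1]


def iopa_run(pathways, gene_summary: OmicsSummary | None,
             compound_summary: OmicsSummary | None,
             combine_method: str = "fisher", n_boot: int = 1000,
             seed: int = 0, n_perm_pbine: int = 1000):
    """Full pathway-analysis pipeline.

    Returns ``(results, manhattan, volcano)``: a list of
    :class:`PathwayResult` (FDR/Bonferroni applied across pathways) plus
    plot-ready tables. A pathway with no mapped feature is reported with
    p = 1, never dropped. Deterministic given ``seed``.
    """
    frames = [s.table for s in (gene_summary, compound_summary)
              if s is not None]
    if not frames:
        raise ValueError("at least one omics summary is required")
    summary = OmicsSummary(pd.concat(frames, ignore_index=True))
    beta = summary.beta_of()
    sig_ids = summary.significant_ids()
    rng = np.random.default_rng(seed)

    null_pairs = None
    if combine_method == "pbine":
        null_pairs = _pbine_null(pathways, summary, n_perm_pbine, rng, n_boot)

    results: list[PathwayResult] = []
    for i, pw in enumerate(pathways):
        pg, cg = pw.members("gene"), pw.members("compound")
        guniv = summary.ids("gene"); cuniv = summary.ids("compound")
        G_n = len(pg & guniv) if guniv else len(pg)
        C_n = len(cg & cuniv) if cuniv else len(cg)
        deG_n = len(pg & sig_ids); deC_n = len(cg & sig_ids)
        if guniv:
            p_g, _ = ora(pw, summary, "gene")
        else:
            p_g = 1.0
        if cuniv:
            p_c, _ = ora(pw, summary, "compound")
        else:
            p_c = 1.0
        p_j, counts = ora(pw, summary, "joint")
        if counts["n"] == 0:
            t_a_v, p_e = 0.0, 1.0
        else:
            de = {nid: beta[nid] for nid in pw.members() & sig_ids
                  if nid in beta}
            t_a_v, p_e = espia(pw, de, n_boot=n_boot,
                               seed=int(rng.integers(2 ** 31)))
        pc = combine_p(p_j, p_e, method=combine_method,
                       null_pairs=null_pairs)
        # normalized perturbation score: t_A over the maximum attainable
        # |t_A| placing the observed effect magnitudes most favourably
        norm = _max_ta(pw, [beta[nid] for nid in pw.members() & sig_ids
                            if nid in beta])
        score = t_a_v / norm if norm > 0 else 0.0
        results.append(PathwayResult(
            pw.pathway_id, pw.name, G_n, deG_n, C_n, deC_n,
            G_n + C_n, deG_n + deC_n, p_g, p_c, p_j, t_a_v, p_e, pc,
            espia_score=score))

    pcs = np.array([r.p_combined for r in results])
    fdr = adjust_p(pcs, "fdr_bh")
    bon = adjust_p(pcs, "bonferroni")
    for r, f, b in zip(results, fdr, bon):
        r.p_fdr = float(f); r.p_bonferroni = float(b)

    manhattan = pd.DataFrame({
        "pathway_id": [r.pathway_id for r in results],
        "name": [r.name for r in results],
        "category": [getattr(pw, "category", "") for pw in pathways],
        "neg_log10_p_fdr": [-np.log10(max(r.p_fdr, np.finfo(float).tiny))
                            for r in results],
    })
    volcano = pd.DataFrame({
        "pathway_id": [r.pathway_id for r in results],
        "espia_score": [r.espia_score for r in results],
        "neg_log10_p": [-np.log10(max(r.p_combined, np.finfo(float).tiny))
                        for r in results],
    })
    return results, manhattan, volcano


def _max_ta(pathway: PathwayGraph, effects) -> float:
    """Maximum |t_A| attainable by assigning the observed |effects| to the
    pathway nodes with the largest per-node accumulation gain."""
    effects = np.abs(np.asarray(list(effects), dtype=float))
    if effects.size == 0:
        return 0.0
    order = sorted(pathway.members())
    nn = len(order)
    B = _propagation_matrix(pathway, order)
    A = np.eye(nn) - B
    if abs(np.linalg.det(A)) < 1e-12:
        A = np.eye(nn) - 0.99 * B
    inv = np.linalg.inv(A)
    # column sums of (inv - I): accumulation generated per unit effect at u
    gain = np.abs((inv - np.eye(nn)).sum(axis=0))
    gain_sorted = np.sort(gain)[::-1]
    eff_sorted = np.sort(effects)[::-1]
    m = min(len(gain_sorted), len(eff_sorted))
    return float((gain_sorted[:m] * eff_sorted[:m]).sum())


def _pbine_null(pathways, summary: OmicsSummary, n_perm: int, rng,
                n_boot: int) -> np.ndarray:
    """Joint null sample of (p_ORA_joint, p_eSPIA) pairs obtained by
    permuting which features carry the significance labels (and their
    effect sizes). Pathways are sampled round-robin to spread the cost."""
    tab = summary.table
    pairs = []
    n_feat = len(tab)
    for b in range(n_perm):
        perm = rng.permutation(n_feat)
        shuffled = tab.copy()
        shuffled["feature_id"] = tab["feature_id"].to_numpy()[perm]
        s2 = OmicsSummary(shuffled)
        pw = pathways[b % len(pathways)]
        p_j, counts = ora(pw, s2, "joint")
        beta = s2.beta_of()
        sig = s2.significant_ids()
        de = {nid: beta[nid] for nid in pw.members() & sig if nid in beta}
        if counts["n"] == 0:
            p_e = 1.0
        else:
            _, p_e = espia(pw, de, n_boot=max(100, n_boot // 4),
                           seed=int(rng.integers(2 ** 31)))
        pairs.append((p_j, p_e))
    return np.asarray(pairs)
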