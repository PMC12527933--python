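"""Kinship estimation, relationship classification and surrogate-parent
clustering.

Kinship uses the robust within-family estimator
``phi = (N_het,het - 2 N_IBS0) / (N_het(a) + N_het(b))`` computed from
0/1/2 genotype matrices, together with IBS0 (the fraction of sites where a
pair shares zero alleles).  Relationship classes follow the standard
half-interval kinship bins (powers of 2^(-k/2)); parent-offspring pairs are
separated from siblings by IBS0 and age difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "KINSHIP_BINS",
    "kinship_ibs",
    "classify_pairs",
    "cluster_surrogate_parents",
    "mendel_error_rate",
    "RelativeSet",
]

#: (lower, upper) kinship bounds per relationship degree.
KINSHIP_BINS = {
    1: (0.1767, 0.3535),
    2: (0.0884, 0.1767),
    3: (0.0442, 0.0884),
    4: (0.0221, 0.0442),
}
IBS0_PO_MAX = 0.0012      # parent-offspring pairs are nearly IBS0-free
AGE_GAP_PARENT = 15.0     # years


def kinship_ibs(
    genotypes: np.ndarray,
    pairs: list[tuple[int, int]] | None = None,
    min_sites: int = 1000,
) -> pd.DataFrame:
    """Pairwise kinship and IBS0 from a (n_individuals, n_sites) 0/1/2 matrix.

    With ``pairs=None`` all pairs are computed via matrix products (the
    indicator cross-counts are inner products).  Pairs with fewer than
    ``min_sites`` jointly called sites are flagged and skipped.
    """
    g = np.asarray(genotypes)
    n, m = g.shape
    het = (g == 1).astype(np.float32)
    hom0 = (g == 0).astype(np.float32)
    hom2 = (g == 2).astype(np.float32)
    if pairs is None:
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    n_hh = het @ het.T
    n_ibs0 = hom0 @ hom2.T + hom2 @ hom0.T
    n_het = het.sum(axis=1)
    rows = []
    for a, b in pairs:
        if m < min_sites:
            rows.append((a, b, np.nan, np.nan, m, True))
            continue
        denom = n_het[a] + n_het[b]
        phi = (n_hh[a, b] - 2.0 * n_ibs0[a, b]) / denom if denom > 0 else np.nan
        rows.append((a, b, phi, n_ibs0[a, b] / m, m, False))
    return pd.DataFrame(
        rows, columns=["a", "b", "kinship", "ibs0", "n_sites", "skipped"]
    )


def classify_pairs(pair_table: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Attach relationship labels to a kinship table.

    ``metadata`` must carry ``age`` indexed like the integer ids in
    ``pair_table`` (columns ``a``/``b``).  First-degree pairs are split into
    parent-offspring (low IBS0, parent >15 years older) and siblings (high
    IBS0, similar age); 2nd-4th degree by kinship bin; else unrelated.
    Missing ages suppress the PO/sibling split but keep the pair.
    """
    ages = metadata["age"]
    out = pair_table.copy()
    phi = out["kinship"].to_numpy(dtype=float)
    ibs0 = out["ibs0"].to_numpy(dtype=float)
    age_a = ages.reindex(out["a"]).to_numpy(dtype=float)
    age_b = ages.reindex(out["b"]).to_numpy(dtype=float)
    dage = np.abs(age_a - age_b)

    labels = np.full(len(out), "unrelated", dtype=object)
    labels[np.isnan(phi)] = "unknown"
    first = (phi >= KINSHIP_BINS[1][0]) & (phi <= KINSHIP_BINS[1][1])
    labels[first] = "first_degree"
    po = first & (ibs0 < IBS0_PO_MAX) & (dage > AGE_GAP_PARENT)
    sib = first & (ibs0 > IBS0_PO_MAX) & (dage < AGE_GAP_PARENT)
    labels[po] = "parent_offspring"
    labels[sib] = "sibling"
    for deg in (2, 3, 4):
        lo, hi = KINSHIP_BINS[deg]
        labels[(phi >= lo) & (phi < hi)] = f"degree{deg}"
    parent = np.where(po,
                      np.where(age_a > age_b, out["a"], out["b"]),
                      None)
    out["relationship"] = labels
    out["parent"] = parent
    return out


@dataclass
class RelativeSet:
    """A target's 2nd-4th-degree relatives split into two family sides."""

    target: object
    g1: set = field(default_factory=set)
    g2: set = field(default_factory=set)
    extra: list = field(default_factory=list)
    ambiguous: bool = False
    degrees: dict = field(default_factory=dict)

    def side_of(self, member) -> str | None:
        if member in self.g1:
            return "G1"
        if member in self.g2:
            return "G2"
        return None


def cluster_surrogate_parents(
    target,
    relatives: dict,
    pair_table: pd.DataFrame,
    related_min_kinship: float = KINSHIP_BINS[4][0],
) -> RelativeSet:
    """Split a target's distant relatives into two surrogate-parent sides.

    ``relatives`` maps relative id -> degree (2-4).  Relatives that are
    themselves related (pairwise kinship above the 4th-degree floor) are
    joined in a graph; connected components become candidate family sides.
    More than two mutually unrelated components is flagged ambiguous; the
    two largest are kept as G1/G2 and the rest reported in ``extra``.
    """
    if not relatives:
        raise ValueError("target has no 2nd-4th degree relatives")
    ids = list(relatives)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    if isinstance(pair_table, dict):
        lookup = pair_table
    else:
        lookup = {}
        for a, b, k in zip(pair_table["a"], pair_table["b"],
                           pair_table["kinship"]):
            lookup[(a, b)] = k
            lookup[(b, a)] = k
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            phi = lookup.get((a, b), np.nan)
            if not np.isnan(phi) and phi >= related_min_kinship:
                graph.add_edge(a, b)
    comps = sorted(nx.connected_components(graph), key=len, reverse=True)
    rs = RelativeSet(target=target, degrees=dict(relatives))
    if len(comps) >= 1:
        rs.g1 = set(comps[0])
    if len(comps) >= 2:
        rs.g2 = set(comps[1])
    if len(comps) > 2:
        rs.ambiguous = True
        rs.extra = [set(c) for c in comps[2:]]
    return rs


def mendel_error_rate(
    child: np.ndarray, father: np.ndarray, mother: np.ndarray
) -> float:
    """Fraction of sites with a Mendelian impossibility in a trio.

    Genotypes are 0/1/2 allele counts on a shared site grid.
    """
    c = np.asarray(child)
    f = np.asarray(father)
    m = np.asarray(mother)
    # transmissible allele-count bounds per parent
    f_min, f_max = (f == 2).astype(int), (f > 0).astype(int)
    m_min, m_max = (m == 2).astype(int), (m > 0).astype(int)
    errors = (c < f_min + m_min) | (c > f_max + m_max)
    return float(errors.mean())
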