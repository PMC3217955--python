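"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (all-pairs scans, union-find, direct
formula application) and shares no code with the implementation under test.
"""

import math
from fractions import Fraction

import numpy as np


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return {frozenset(g) for g in groups.values()}


def _best_hit_per_pair(hits):
    best = {}
    for h in hits:
        key = (h.query, h.subject)
        cur = best.get(key)
        if cur is None or (h.bitscore, -h.evalue, h.percent_identity) > (
            cur.bitscore,
            -cur.evalue,
            cur.percent_identity,
        ):
            best[key] = h
    return list(best.values())


def naive_jaccard_partition(proteome, hits, params, genome_of):
    """All-pairs Jaccard clustering of one genome via union-find."""
    kept = [
        h
        for h in _best_hit_per_pair(hits)
        if genome_of[h.query] == proteome.genome_id
        and genome_of[h.subject] == proteome.genome_id
        and h.query != h.subject
        and h.evalue <= params.max_evalue
        and h.percent_identity >= params.min_identity_percent
    ]
    match = {p: {p} for p in proteome.proteins}
    for h in kept:
        match[h.query].add(h.subject)
        match[h.subject].add(h.query)
    uf = UnionFind(proteome.proteins)
    proteins = sorted(proteome.proteins)
    for i, a in enumerate(proteins):
        for b in proteins[i + 1 :]:
            union = match[a] | match[b]
            j = len(match[a] & match[b]) / len(union) if union else 0.0
            if j > params.jaccard_threshold:
                uf.union(a, b)
    return uf.components()


def naive_ortholog_components(proteomes, hits, params):
    """End-to-end oracle: Jaccard partitions, cluster RBH, components.

    Returns (per-genome partitions, set of ortholog components given as
    frozensets of (genome, protein)).
    """
    genome_of = {p: pr.genome_id for pr in proteomes for p in pr.proteins}
    partitions = {
        pr.genome_id: naive_jaccard_partition(pr, hits, params, genome_of)
        for pr in proteomes
    }
    clusters = []  # (key, genome, members)
    for genome, parts in sorted(partitions.items()):
        for members in sorted(parts, key=min):
            clusters.append((f"{genome}:{min(members)}", genome, members))
    cluster_of = {p: key for key, _, members in clusters for p in members}

    ortho = [
        h
        for h in _best_hit_per_pair(hits)
        if h.evalue <= params.max_evalue
        and genome_of[h.query] != genome_of[h.subject]
    ]

    def best_subjects(protein, genome):
        top, out = -math.inf, set()
        for h in ortho:
            if h.query == protein and genome_of[h.subject] == genome:
                if h.bitscore > top:
                    top, out = h.bitscore, {h.subject}
                elif h.bitscore == top:
                    out.add(h.subject)
        return out

    def cluster_best(members, genome):
        out = set()
        for p in members:
            out |= best_subjects(p, genome)
        return out

    uf = UnionFind([key for key, _, _ in clusters])
    for key_a, genome_a, members_a in clusters:
        for key_b, genome_b, members_b in clusters:
            if key_a >= key_b or genome_a == genome_b:
                continue
            ab = cluster_best(members_a, genome_b) & members_b
            ba = cluster_best(members_b, genome_a) & members_a
            if ab and ba:
                uf.union(key_a, key_b)
    members_of = {key: members for key, _, members in clusters}
    genome_of_cluster = {key: genome for key, genome, _ in clusters}
    components = set()
    for component in uf.components():
        if len(component) < 2:
            continue
        components.add(
            frozenset(
                (genome_of_cluster[key], protein)
                for key in component
                for protein in members_of[key]
            )
        )
    return partitions, components


def hypergeom_upper_tail(k, n, K, N):
    """Exact upper-tail probability by rational enumeration of the pmf."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return float(total)


def bh_step_up(pvalues):
    """Benjamini-Hochberg step-up q-values by the textbook formula."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def random_clustering_instance(rng):
    """A random multi-genome proteome + hit table for oracle comparison."""
    from orthogo.clustering import Proteome, SimilarityHit

    n_genomes = int(rng.integers(2, 5))
    proteomes = []
    all_proteins = []
    for gi in range(n_genomes):
        size = int(rng.integers(1, 16))
        proteins = [f"g{gi}_p{j}" for j in range(size)]
        proteomes.append(Proteome(f"g{gi}", frozenset(proteins)))
        all_proteins.extend(proteins)
    hits = []
    n_hits = int(rng.integers(0, 80))
    if len(all_proteins) >= 2:
        for _ in range(n_hits):
            q, s = rng.choice(len(all_proteins), size=2, replace=False)
            hits.append(
                SimilarityHit(
                    query=all_proteins[int(q)],
                    subject=all_proteins[int(s)],
                    percent_identity=float(rng.choice([60.0, 79.9, 80.0, 95.0])),
                    evalue=float(rng.choice([1e-30, 1e-6, 1e-5, 1e-3])),
                    # coarse grid => frequent ties, exercising the tie rules
                    bitscore=float(rng.integers(5, 15) * 10),
                )
            )
    return proteomes, hits
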