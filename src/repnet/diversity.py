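"""Chain expression, Shannon entropy and Pielou evenness per sample x chain.

Expression is the fraction of a sample's sequenced reads assigned to each
immunoglobulin chain. Diversity is computed over clones (read-weighted
proportions p_i): Shannon entropy H = -sum p_i log2 p_i, ranging from 0 for
a single clone to log2 N for a uniform repertoire of N clones, and Pielou
evenness J = H / log2 N, in [0, 1] and undefined (missing) for N <= 1.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .io import IG_CHAINS, ClonotypeRecord, SampleManifestEntry
from .network import build_network, call_clones, cluster_gini, vertex_gini

FEATURE_COLUMNS = [
    "expression",
    "entropy_H",
    "evenness_J",
    "vertex_gini",
    "cluster_gini",
]


def chain_expression(chain_reads: int, total_reads: int) -> float:
    """Reads aligned to one chain divided by the sample's total reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if chain_reads < 0:
        raise ValueError("chain_reads must be non-negative")
    if chain_reads > total_reads:
        raise IntegrityError(
            f"chain reads ({chain_reads}) exceed total reads ({total_reads})"
        )
    return chain_reads / total_reads


def shannon_entropy(clone_counts: Sequence[int]) -> float:
    """Shannon entropy (bits) of read-weighted clone proportions."""
    counts = np.asarray(clone_counts, dtype=float)
    if counts.size == 0:
        return float("nan")
    if np.any(counts <= 0):
        raise ValueError("clone counts must be positive")
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)) + 0.0)  # +0.0 avoids returning -0.0


def pielou_evenness(clone_counts: Sequence[int]) -> float:
    """Entropy normalized by its maximum log2 N; missing when N = 1."""
    counts = np.asarray(clone_counts, dtype=float)
    if counts.size == 0:
        return float("nan")
    if counts.size == 1:
        return float("nan")  # H_max = 0, ratio undefined
    return shannon_entropy(clone_counts) / float(np.log2(counts.size))


def feature_table(
    records_by_sample: Mapping[str, Sequence[ClonotypeRecord]],
    manifest: Sequence[SampleManifestEntry],
) -> pd.DataFrame:
    """Assemble the tidy per-sample, per-chain repertoire feature table.

    One row per manifest sample per Ig chain (3 x samples rows). Chains with
    no records get expression 0 and missing diversity/network metrics.
    """
    rows = []
    for entry in manifest:
        recs = records_by_sample.get(entry.sample_id, [])
        by_chain: dict[str, list[ClonotypeRecord]] = {c: [] for c in IG_CHAINS}
        for r in recs:
            by_chain[r.chain].append(r)
        for chain in IG_CHAINS:
            chain_recs = by_chain[chain]
            n_reads = sum(r.read_count for r in chain_recs)
            row = {
                "sample_id": entry.sample_id,
                "tumor_type": entry.tumor_type,
                "chain": chain,
                "n_reads": n_reads,
                "expression": chain_expression(n_reads, entry.total_reads),
                "n_clones": 0,
                "entropy_H": float("nan"),
                "evenness_J": float("nan"),
                "vertex_gini": float("nan"),
                "cluster_gini": float("nan"),
            }
            if chain_recs:
                net = build_network(chain_recs)
                clones = call_clones(net)
                row.update(
                    n_clones=clones.n_clones,
                    entropy_H=shannon_entropy(clones.counts()),
                    evenness_J=pielou_evenness(clones.counts()),
                    vertex_gini=vertex_gini(net),
                    cluster_gini=cluster_gini(net),
                )
            rows.append(row)
    return pd.DataFrame(rows)
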