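"""Frequent subgraph mining over chain-graph corpora.

Each patient-variable chain is a linear path of integer levels, so frequent
subgraph mining reduces to mining contiguous level runs (length 2-6 by
default). Mining is Apriori-style: patterns of length m are extended one level
at a time, pruned by the anti-monotonicity of support (a pattern can only be
frequent if its length-(m-1) prefix is). Support counts distinct chains
(document frequency); per-patient feature values count occurrences, with
overlapping occurrences all counted.

After the per-variable results are column-concatenated into a patient x
subgraph count matrix, subgraph isomorphism removal zeroes, independently per
patient, every pattern that is a contiguous sub-pattern of a larger pattern
also present for that patient; columns that become all-zero are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

Chain = tuple[int, ...]
Pattern = tuple[int, ...]


@dataclass(frozen=True)
class Subgraph:
    """A variable-tagged contiguous run of integer levels."""

    variable: str
    levels: Pattern

    @property
    def id(self) -> str:
        return f"{self.variable}:{','.join(str(v) for v in self.levels)}"

    def __len__(self) -> int:
        return len(self.levels)


@dataclass
class MiningResult:
    """Frequent patterns of one variable's corpus."""

    variable: str
    patterns: list[Pattern]                      # sorted canonically
    support: dict[Pattern, int]                  # distinct chains containing
    counts: dict[Pattern, dict[str, int]]        # pattern -> patient -> occurrences


@dataclass
class SubgraphCountMatrix:
    patients: list[str]
    subgraphs: list[Subgraph]
    counts: sp.csr_matrix                        # patients x subgraphs, ints
    support: np.ndarray                          # per column, chain support
    n_mined: int = 0
    n_dropped: int = 0

    @property
    def n_retained(self) -> int:
        return len(self.subgraphs)

    def column_index(self) -> dict[str, int]:
        return {s.id: j for j, s in enumerate(self.subgraphs)}


def enumerate_occurrences(chain: Sequence[int], pattern: Sequence[int]) -> int:
    """Number of start positions where ``pattern`` matches ``chain``
    contiguously; overlapping occurrences all count. Direction matters."""
    m, k = len(chain), len(pattern)
    if k == 0:
        raise ValueError("pattern must have length >= 1")
    if k > m:
        return 0
    pat = tuple(pattern)
    return sum(1 for p in range(m - k + 1) if tuple(chain[p:p + k]) == pat)


def mine_corpus(
    corpus: Mapping[str, Chain],
    min_support: int,
    min_size: int = 2,
    max_size: int = 6,
    variable: str = "",
) -> MiningResult:
    """All contiguous patterns of length in [min_size, max_size] contained in
    at least ``min_support`` distinct chains, with supports and per-patient
    occurrence counts.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if not 1 <= min_size <= max_size:
        raise ValueError("need 1 <= min_size <= max_size")

    support: dict[Pattern, int] = {}
    counts: dict[Pattern, dict[str, int]] = {}

    # frequent length-1 seeds
    frequent_prev = _mine_level(corpus, 1, None, min_support, support, counts)
    if min_size == 1:
        keep_from = 1
    else:
        keep_from = min_size
    for size in range(2, max_size + 1):
        if not frequent_prev:
            break
        frequent_prev = _mine_level(corpus, size, frequent_prev, min_support,
                                    support, counts)

    patterns = sorted(
        p for p in support if keep_from <= len(p) <= max_size
    )
    return MiningResult(
        variable=variable,
        patterns=patterns,
        support={p: support[p] for p in patterns},
        counts={p: counts[p] for p in patterns},
    )


def _mine_level(corpus, size, frequent_prev, min_support, support, counts):
    """Count all length-``size`` windows whose (size-1)-prefix is frequent;
    return the set of frequent patterns found at this size."""
    level_support: dict[Pattern, set] = {}
    level_counts: dict[Pattern, dict[str, int]] = {}
    for pid, chain in corpus.items():
        for p in range(len(chain) - size + 1):
            pat = tuple(chain[p:p + size])
            if frequent_prev is not None and pat[:-1] not in frequent_prev:
                continue  # anti-monotone pruning on the prefix
            level_support.setdefault(pat, set()).add(pid)
            pc = level_counts.setdefault(pat, {})
            pc[pid] = pc.get(pid, 0) + 1
    frequent = set()
    for pat, chains in level_support.items():
        if len(chains) >= min_support:
            frequent.add(pat)
            support[pat] = len(chains)
            counts[pat] = level_counts[pat]
    return frequent


def _is_proper_subpattern(small: Pattern, big: Pattern) -> bool:
    if len(small) >= len(big):
        return False
    k = len(small)
    return any(big[i:i + k] == small for i in range(len(big) - k + 1))


def remove_subsumed(matrix: SubgraphCountMatrix) -> SubgraphCountMatrix:
    """Patient-level subsumption removal.

    For each patient independently, let P be the set of patterns with nonzero
    count *before* removal; the count of every pattern in P that is a
    contiguous sub-pattern (same variable) of a larger pattern in P is set to
    0. Maximality is judged against the original presence set P, never the
    progressively zeroed one, so the operation is idempotent. Columns whose
    total count drops to zero are removed; the number dropped is recorded.
    """
    lil = matrix.counts.tolil(copy=True)
    cols_by_var: dict[str, list[int]] = {}
    for j, s in enumerate(matrix.subgraphs):
        cols_by_var.setdefault(s.variable, []).append(j)

    csr = matrix.counts.tocsr()
    for i in range(csr.shape[0]):
        row_cols = csr.indices[csr.indptr[i]:csr.indptr[i + 1]]
        if row_cols.size < 2:
            continue
        present: dict[str, list[int]] = {}
        for j in row_cols:
            present.setdefault(matrix.subgraphs[j].variable, []).append(j)
        for var, js in present.items():
            if len(js) < 2:
                continue
            pats = [matrix.subgraphs[j].levels for j in js]
            for j, pat in zip(js, pats):
                if any(_is_proper_subpattern(pat, other) for other in pats):
                    lil[i, j] = 0

    pruned = lil.tocsc()
    col_totals = np.asarray(pruned.sum(axis=0)).ravel()
    keep = np.flatnonzero(col_totals > 0)
    n_dropped_now = pruned.shape[1] - keep.size
    if n_dropped_now:
        logger.info("subsumption removal dropped %d all-zero column(s)", n_dropped_now)
    return SubgraphCountMatrix(
        patients=list(matrix.patients),
        subgraphs=[matrix.subgraphs[j] for j in keep],
        counts=pruned[:, keep].tocsr(),
        support=matrix.support[keep],
        n_mined=matrix.n_mined or matrix.counts.shape[1],
        n_dropped=matrix.n_dropped + n_dropped_now,
    )


def assemble_matrix(
    results: Sequence[MiningResult],
    patients: Sequence[str],
    apply_subsumption: bool = True,
) -> SubgraphCountMatrix:
    """Column-concatenate per-variable mining results over a fixed patient
    universe, then apply patient-level subsumption removal.

    Patients absent from every corpus keep an all-zero row. Reports the
    bookkeeping mined = dropped + retained.
    """
    patients = list(patients)
    row_of = {pid: i for i, pid in enumerate(patients)}
    subgraphs: list[Subgraph] = []
    supports: list[int] = []
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    seen_ids: set[str] = set()
    for res in results:
        for pat in res.patterns:
            s = Subgraph(res.variable, pat)
            if s.id in seen_ids:
                raise RuntimeError(f"duplicate subgraph id {s.id!r}")
            seen_ids.add(s.id)
            j = len(subgraphs)
            subgraphs.append(s)
            supports.append(res.support[pat])
            for pid, c in res.counts[pat].items():
                if pid not in row_of:
                    raise KeyError(f"patient {pid!r} outside the patient universe")
                rows.append(row_of[pid])
                cols.append(j)
                vals.append(c)
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(patients), len(subgraphs)), dtype=np.int64
    )
    matrix = SubgraphCountMatrix(
        patients=patients,
        subgraphs=subgraphs,
        counts=counts,
        support=np.asarray(supports, dtype=np.int64),
        n_mined=len(subgraphs),
        n_dropped=0,
    )
    if apply_subsumption:
        matrix = remove_subsumed(matrix)
        logger.info(
            "assemble_matrix: mined %d, dropped %d, retained %d",
            matrix.n_mined, matrix.n_dropped, matrix.n_retained,
        )
    return matrix


def mine_all(
    corpora: Mapping[str, Mapping[str, Chain]],
    min_support: int,
    min_size: int = 2,
    max_size: int = 6,
    patients: Sequence[str] | None = None,
) -> SubgraphCountMatrix:
    """Mine every variable's corpus and assemble the final count matrix."""
    if patients is None:
        universe: set[str] = set()
        for corpus in corpora.values():
            universe.update(corpus)
        patients = sorted(universe)
    results = [
        mine_corpus(corpora[var], min_support, min_size, max_size, variable=var)
        for var in sorted(corpora)
    ]
    return assemble_matrix(results, patients)


# ---------------------------------------------------------------------------
# disk round-trip: MatrixMarket + sidecar CSVs


def write_matrix(matrix: SubgraphCountMatrix, out_dir) -> None:
    from pathlib import Path

    import pandas as pd
    from scipy.io import mmwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "counts.mtx", matrix.counts)
    pd.DataFrame({"patient_id": matrix.patients}).to_csv(out / "rows.csv", index=False)
    pd.DataFrame({
        "subgraph_id": [s.id for s in matrix.subgraphs],
        "variable": [s.variable for s in matrix.subgraphs],
        "levels": [",".join(map(str, s.levels)) for s in matrix.subgraphs],
        "support": matrix.support,
    }).to_csv(out / "columns.csv", index=False)


def read_matrix(in_dir) -> SubgraphCountMatrix:
    from pathlib import Path

    import pandas as pd
    from scipy.io import mmread

    src = Path(in_dir)
    counts = sp.csr_matrix(mmread(src / "counts.mtx"))
    rows = pd.read_csv(src / "rows.csv")
    cols = pd.read_csv(src / "columns.csv")
    subgraphs = [
        Subgraph(v, tuple(int(x) for x in str(lv).split(",")))
        for v, lv in zip(cols["variable"], cols["levels"])
    ]
    return SubgraphCountMatrix(
        patients=list(rows["patient_id"]),
        subgraphs=subgraphs,
        counts=counts,
        support=cols["support"].to_numpy(),
        n_mined=counts.shape[1],
    )
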