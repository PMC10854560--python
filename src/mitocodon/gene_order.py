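"""Gene-order signatures, rearrangement diffs, and spacer/overlap tallies.

A signature is the rotation-normalized list of (name, strand) pairs read
along the forward strand, anchored at trnF (the vertebrate convention);
when trnF is absent, the lexicographically smallest feature name anchors
instead. Order diffs align two signatures by longest common subsequence:
elements only in the first are deletions, only in the second insertions,
and shared elements outside the LCS are translocations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GeneFeature, MitogenomeRecord


@dataclass(frozen=True)
class OrderSignature:
    elements: tuple[tuple[str, str], ...]  # (canonical name, strand)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.elements)

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class OrderDiff:
    deletions: tuple[str, ...]  # only in a
    insertions: tuple[str, ...]  # only in b
    translocations: tuple[str, ...]  # shared but outside the LCS

    @property
    def is_empty(self) -> bool:
        return not (self.deletions or self.insertions or self.translocations)

    @property
    def edit_count(self) -> int:
        return len(self.deletions) + len(self.insertions) + len(self.translocations)


def gene_order_signature(record: MitogenomeRecord) -> OrderSignature:
    """Coordinate-sorted feature order, rotated to start at trnF."""
    if len(record.features) < 2:
        raise ValueError(f"{record.accession}: need at least 2 features")
    feats = sorted(record.features, key=lambda f: (f.start, f.end, f.name))
    names = [f.name for f in feats]
    if "trnF" in names:
        pivot = names.index("trnF")
    else:
        pivot = names.index(min(names))
    rotated = feats[pivot:] + feats[:pivot]
    return OrderSignature(tuple((f.name, f.strand) for f in rotated))


def _lcs_names(a: tuple[str, ...], b: tuple[str, ...]) -> set[str]:
    """Names participating in one longest common subsequence (standard DP)."""
    la, lb = len(a), len(b)
    dp = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la - 1, -1, -1):
        for j in range(lb - 1, -1, -1):
            if a[i] == b[j]:
                dp[i][j] = dp[i + 1][j + 1] + 1
            else:
                dp[i][j] = max(dp[i + 1][j], dp[i][j + 1])
    out = set()
    i = j = 0
    while i < la and j < lb:
        if a[i] == b[j]:
            out.add(a[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return out


def diff_gene_orders(a: OrderSignature, b: OrderSignature) -> OrderDiff:
    """Insertions / deletions / translocations between two signatures."""
    names_a, names_b = a.names, b.names
    set_a, set_b = set(names_a), set(names_b)
    shared_a = tuple(n for n in names_a if n in set_b)
    shared_b = tuple(n for n in names_b if n in set_a)
    lcs = _lcs_names(shared_a, shared_b)
    return OrderDiff(
        deletions=tuple(n for n in names_a if n not in set_b),
        insertions=tuple(n for n in names_b if n not in set_a),
        translocations=tuple(n for n in shared_a if n not in lcs),
    )


@dataclass(frozen=True)
class Adjacency:
    upstream: str
    downstream: str
    length: int  # spacer length (gap > 0) or overlap length (gap < 0)


def spacer_overlap_tally(
    record: MitogenomeRecord, include_control_region: bool = False
) -> tuple[list[Adjacency], list[Adjacency]]:
    """Spacers and overlaps between circularly consecutive features.

    The control region is excluded from the adjacency chain by default
    (it is an annotated feature in its own right, not a spacer); origins,
    PCGs, tRNAs and rRNAs all participate.
    """
    feats = [
        f
        for f in record.features
        if include_control_region or f.feature_class != "control_region"
    ]
    if len(feats) < 2:
        raise ValueError("need at least 2 chained features")
    feats = sorted(feats, key=lambda f: (f.start, f.end, f.name))
    n = len(record.sequence)
    spacers: list[Adjacency] = []
    overlaps: list[Adjacency] = []
    for current, following in zip(feats, feats[1:] + feats[:1]):
        gap = following.start - current.end
        if following is feats[0]:  # wrap across the circular origin
            gap += n
        if gap > 0:
            spacers.append(Adjacency(current.name, following.name, gap))
        elif gap < 0:
            overlaps.append(Adjacency(current.name, following.name, -gap))
    return spacers, overlaps


def layout_table(record: MitogenomeRecord) -> str:
    """Plain linear gene-map layout as TSV: name, class, strand, start, end."""
    lines = ["name\tclass\tstrand\tstart\tend"]
    for feat in sorted(record.features, key=lambda f: f.start):
        lines.append(
            f"{feat.name}\t{feat.feature_class}\t{feat.strand}\t{feat.start}\t{feat.end}"
        )
    return "\n".join(lines) + "\n"
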