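"""UMI error correction and count-matrix construction.

Unique molecular identifiers (UMIs) acquire sequencing errors that
inflate molecule counts, especially at very deep sequencing.  Within
each (cell barcode, gene) group this module clusters UMI sequences with
the directional adjacency network: a directed edge runs a -> b when the
sequences differ at exactly one position (Hamming distance 1) and
``reads_a >= 2 * reads_b - 1``, and each cluster is the set reachable
from an unclaimed highest-read seed.  The corrected molecule count of
the group is the number of clusters.

A second, deliberately faulty scheme — each UMI independently
reassigned to a strictly-more-read Hamming-1 neighbor, with no chaining
— is provided for regression comparisons: it can "correct" an
erroneous UMI toward another erroneous UMI (e.g. with AAAA:10 reads,
AAAT:2, AATT:1, AATT becomes AAAT while AAAT itself becomes AAAA,
leaving two distinct UMIs where one molecule existed).
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import InvalidGroupError, ParseError
from .io import CountMatrix

__all__ = [
    "UmiRecord",
    "UmiGroupResult",
    "directional_clusters",
    "onepass_correction",
    "read_umi_records",
    "count_matrix_from_records",
]

_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class UmiRecord:
    """One read-level record: a UMI seen `reads` times for (cell, gene)."""

    cell_barcode: str
    gene_id: str
    umi: str
    reads: int


@dataclass(frozen=True)
class UmiGroupResult:
    """Partition of one (cell, gene) group's UMIs into molecule clusters."""

    clusters: tuple[tuple[str, ...], ...]
    representatives: tuple[str, ...]

    @property
    def corrected_umi_count(self) -> int:
        return len(self.clusters)


def _validate_group(group: Sequence[tuple[str, int]]) -> None:
    if not group:
        raise InvalidGroupError("empty UMI group")
    length = len(group[0][0])
    for umi, reads in group:
        if len(umi) != length:
            raise InvalidGroupError(
                f"mixed UMI lengths in group: {group[0][0]!r} vs {umi!r}"
            )
        if set(umi) - _ALPHABET:
            raise InvalidGroupError(f"UMI {umi!r} not over alphabet ACGT")
        if reads <= 0:
            raise InvalidGroupError(f"UMI {umi!r} has nonpositive read count")


def _hamming1(a: str, b: str) -> bool:
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > 1:
                return False
    return mismatches == 1


def directional_clusters(group: Sequence[tuple[str, int]]) -> UmiGroupResult:
    """Directional adjacency clustering of one UMI group.

    UMIs are taken as cluster seeds in descending read order (ties
    lexicographic); each cluster grows breadth-first along directed
    edges a -> b with Hamming(a, b) = 1 and reads_a >= 2*reads_b - 1,
    claiming each UMI at most once.
    """
    _validate_group(group)
    reads = dict(group)
    if len(reads) != len(group):
        raise InvalidGroupError("duplicate UMI in group")
    order = sorted(reads, key=lambda u: (-reads[u], u))
    claimed: set[str] = set()
    clusters: list[tuple[str, ...]] = []
    reps: list[str] = []
    for seed in order:
        if seed in claimed:
            continue
        members = [seed]
        claimed.add(seed)
        queue = [seed]
        while queue:
            a = queue.pop(0)
            # deterministic expansion: scan candidates in seed order
            for b in order:
                if b in claimed:
                    continue
                if _hamming1(a, b) and reads[a] >= 2 * reads[b] - 1:
                    claimed.add(b)
                    members.append(b)
                    queue.append(b)
        clusters.append(tuple(members))
        reps.append(seed)
    return UmiGroupResult(clusters=tuple(clusters), representatives=tuple(reps))


def onepass_correction(group: Sequence[tuple[str, int]]) -> dict[str, str]:
    """Single simultaneous pass of naive UMI correction (faulty by design).

    Every UMI is independently mapped to the Hamming-1 neighbor with
    strictly more reads that satisfies the directional threshold
    (reads_neighbor >= 2*reads_umi - 1), choosing the highest-read such
    neighbor (ties lexicographic), or to itself.  Assignments are
    simultaneous, so chains are not followed and a UMI can be corrected
    toward a neighbor that is itself being corrected away.
    """
    _validate_group(group)
    reads = dict(group)
    if len(reads) != len(group):
        raise InvalidGroupError("duplicate UMI in group")
    corrected: dict[str, str] = {}
    for umi in reads:
        best = None
        for other in reads:
            if (
                other != umi
                and _hamming1(umi, other)
                and reads[other] > reads[umi]
                and reads[other] >= 2 * reads[umi] - 1
            ):
                if best is None or (-reads[other], other) < (-reads[best], best):
                    best = other
        corrected[umi] = best if best is not None else umi
    return corrected


def read_umi_records(path: str | Path) -> list[UmiRecord]:
    """Parse a read-level TSV with header cell_barcode, gene_id, umi, reads."""
    path = Path(path)
    records: list[UmiRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file", line_number=0)
        expected = ["cell_barcode", "gene_id", "umi", "reads"]
        if [h.strip() for h in header] != expected:
            raise ParseError(
                f"{path}: header must be {expected}, got {header}", line_number=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 fields, got {len(row)}",
                    line_number=lineno,
                )
            try:
                reads = int(row[3])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: reads column not an integer: {row[3]!r}",
                    line_number=lineno,
                )
            records.append(UmiRecord(row[0], row[1], row[2], reads))
    return records


def count_matrix_from_records(
    records: Iterable[UmiRecord],
    method: Literal["directional", "onepass", "none"] = "directional",
) -> CountMatrix:
    """Build a genes x cells molecule-count matrix from UMI records.

    The entry for (gene, cell) is the number of UMI clusters
    (method="directional"), the number of distinct one-pass-corrected
    UMIs (method="onepass"), or the number of distinct raw UMIs
    (method="none").  Gene and cell identifiers are sorted; zero pairs
    are absent from the sparse matrix.
    """
    groups: dict[tuple[str, str], dict[str, int]] = defaultdict(dict)
    for rec in records:
        key = (rec.cell_barcode, rec.gene_id)
        groups[key][rec.umi] = groups[key].get(rec.umi, 0) + rec.reads

    genes = sorted({g for _, g in groups})
    cells = sorted({c for c, _ in groups})
    gene_idx = {g: i for i, g in enumerate(genes)}
    cell_idx = {c: i for i, c in enumerate(cells)}

    rows, cols, vals = [], [], []
    for (cell, gene), umis in groups.items():
        group = sorted(umis.items())
        if method == "directional":
            n = directional_clusters(group).corrected_umi_count
        elif method == "onepass":
            n = len(set(onepass_correction(group).values()))
        elif method == "none":
            n = len(group)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(gene_idx[gene])
        cols.append(cell_idx[cell])
        vals.append(n)

    matrix = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(genes), len(cells)), dtype=np.int64
    )
    return CountMatrix(
        gene_ids=np.array(genes, dtype=object),
        barcodes=np.array(cells, dtype=object),
        matrix=matrix,
    )
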