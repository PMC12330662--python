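"""Barcode demultiplexing of raw long reads.

Reads are assigned to samples by first locating the poly-T tract of the
oligo-dT primer and the common primer (CP), then searching a window adjacent
to those anchors for a unique barcode at infix edit distance <= 3
(Levenshtein, since nanopore errors include indels). Reads with no barcode,
more than one matching barcode, or conflicting anchor orientations are
excluded from downstream analysis. Identified barcode, poly-T and CP
segments are trimmed and the internal cDNA returned in transcript sense.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .models import revcomp

DEFAULT_MAX_DIST = 3
DEFAULT_MIN_POLYT = 10
POLYT_MIN_FRAC = 0.9
POLYT_MAX_WINDOW = 60  # longest tract considered; real oligo-dT tracts are far shorter
BARCODE_WINDOW_SLACK = 8  # search window is barcode length + this many bases
BARCODE_WINDOW_OVERLAP = 4  # window reaches this far past the poly-T start, so a
# barcode whose T-rich suffix was swallowed by the poly-T window still matches


@dataclass(frozen=True)
class PolyTHit:
    start: int
    end: int
    orientation: str  # forward | reverse (coordinates on the stated orientation)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrimerHit:
    start: int
    end: int
    distance: int
    orientation: str


@dataclass
class BarcodeAssignment:
    """Outcome of demultiplexing one read.

    ``status`` is one of assigned / none_found / multiple_found; only
    assigned reads proceed downstream. ``trimmed`` holds the insert after
    anchor removal (the unmodified read, flagged, when unassigned).
    """

    read_id: str
    status: str
    barcode_id: str = ""
    distance: int = -1
    orientation: str = ""
    trimmed: str = ""
    trimmed_ok: bool = False
    reason: str = ""
    # anchor loci on the oriented read, used by trim_read
    polyt: PolyTHit | None = None
    cp: PrimerHit | None = None
    barcode_locus: tuple[int, int] | None = None


def _longest_t_window(seq: str, min_run: int, min_frac: float, max_window: int) -> tuple[int, int] | None:
    """Longest window of length >= min_run whose T content is >= min_frac,
    shrunk to T boundaries. Leftmost window wins at equal length."""
    n = len(seq)
    if n < min_run:
        return None
    is_t = np.frombuffer(seq.encode(), dtype="S1") == b"T"
    cs = np.concatenate(([0], np.cumsum(is_t)))
    top = min(n, max_window)
    for L in range(top, min_run - 1, -1):
        need = int(np.ceil(min_frac * L))
        counts = cs[L:] - cs[:-L]
        idx = np.flatnonzero(counts >= need)
        if idx.size:
            s = int(idx[0])
            e = s + L
            while s < e and not is_t[s]:
                s += 1
            while e > s and not is_t[e - 1]:
                e -= 1
            if e - s >= min_run:
                return (s, e)
    return None


def find_polyt(
    read: str,
    min_run: int = DEFAULT_MIN_POLYT,
    min_frac: float = POLYT_MIN_FRAC,
    max_window: int = POLYT_MAX_WINDOW,
) -> PolyTHit | None:
    """Locate the poly-T tract on the read or its reverse complement.

    Returns the longest T-dominated window (>= ``min_frac`` T over >=
    ``min_run`` bases); the orientation carrying the longer window wins, the
    forward read on ties.
    """
    if not read:
        raise ValueError("read must be non-empty")
    fwd = _longest_t_window(read, min_run, min_frac, max_window)
    rev = _longest_t_window(revcomp(read), min_run, min_frac, max_window)
    if fwd is None and rev is None:
        return None
    if rev is None or (fwd is not None and fwd[1] - fwd[0] >= rev[1] - rev[0]):
        return PolyTHit(fwd[0], fwd[1], "forward")
    return PolyTHit(rev[0], rev[1], "reverse")


def _best_infix(query: str, target: str, max_dist: int) -> tuple[int, int, int] | None:
    """Best infix (semi-global) edit-distance locus of query in target."""
    if not target:
        return None
    res = edlib.align(query, target, mode="HW", task="locations", k=max_dist)
    if res["editDistance"] < 0:
        return None
    s, e = res["locations"][0]
    return (s, e + 1, res["editDistance"])


def find_common_primer(read: str, cp: str, max_dist: int = DEFAULT_MAX_DIST) -> PrimerHit | None:
    """Best CP locus across both strands.

    In the forward read layout the CP appears reverse-complemented near the
    read's 3' end, so a hit of revcomp(cp) on the read implies forward
    orientation, while a hit of cp itself implies the reverse. Equal
    distances on both strands are ambiguous and return no hit.
    """
    if len(cp) < 10:
        raise ValueError("common primer must be at least 10 nt")
    hit_f = _best_infix(revcomp(cp), read, max_dist)
    hit_r = _best_infix(cp, read, max_dist)
    if hit_f is None and hit_r is None:
        return None
    if hit_r is None or (hit_f is not None and hit_f[2] < hit_r[2]):
        return PrimerHit(hit_f[0], hit_f[1], hit_f[2], "forward")
    if hit_f is None or hit_r[2] < hit_f[2]:
        # reverse layout: report coordinates on the oriented (revcomp) read
        n = len(read)
        return PrimerHit(n - hit_r[1], n - hit_r[0], hit_r[2], "reverse")
    return None  # tie between orientations: ambiguous


def assign_barcode(
    read_id: str,
    read: str,
    barcodes: Mapping[str, str],
    cp: str | None = None,
    max_dist: int = DEFAULT_MAX_DIST,
    min_polyt: int = DEFAULT_MIN_POLYT,
) -> BarcodeAssignment:
    """Assign a read to a barcode using poly-T / CP anchored infix search.

    The barcode is searched in a window of barcode length + 8 bases
    immediately 5' of the poly-T tract, in the orientation the anchors imply;
    failing a poly-T hit, a window at the CP-distal end of the read is used.
    Exactly one barcode within edit distance ``max_dist`` => assigned; zero
    => none_found; two or more (including distance ties) => multiple_found.
    Conflicting poly-T / CP orientations => none_found.
    """
    if not barcodes:
        raise ValueError("barcode set must be non-empty")
    polyt = find_polyt(read, min_run=min_polyt)
    cp_hit = find_common_primer(read, cp, max_dist) if cp else None
    if polyt is not None and cp_hit is not None and polyt.orientation != cp_hit.orientation:
        return BarcodeAssignment(
            read_id, "none_found", reason="anchor orientation conflict", trimmed=read
        )
    orientation = polyt.orientation if polyt is not None else (
        cp_hit.orientation if cp_hit is not None else ""
    )
    if not orientation:
        return BarcodeAssignment(read_id, "none_found", reason="no anchors", trimmed=read)
    oriented = read if orientation == "forward" else revcomp(read)

    bc_len = max(len(b) for b in barcodes.values())
    window: tuple[int, int] | None = None
    if polyt is not None:
        window = (
            max(0, polyt.start - (bc_len + BARCODE_WINDOW_SLACK)),
            min(len(oriented), polyt.start + BARCODE_WINDOW_OVERLAP),
        )
    hits = _match_barcodes(oriented, window, barcodes, max_dist) if window else {}
    if not hits and cp_hit is not None:
        # symmetric logic from the CP: the barcode sits at the CP-distal end
        window = (0, bc_len + BARCODE_WINDOW_SLACK)
        hits = _match_barcodes(oriented, window, barcodes, max_dist)
    if not hits:
        return BarcodeAssignment(
            read_id, "none_found", orientation=orientation, reason="no barcode within tolerance",
            trimmed=read, polyt=polyt, cp=cp_hit,
        )
    if len(hits) > 1:
        return BarcodeAssignment(
            read_id, "multiple_found", orientation=orientation,
            reason=f"{len(hits)} barcodes within tolerance", trimmed=read,
            polyt=polyt, cp=cp_hit,
        )
    (bc_id, (dist, locus)) = next(iter(hits.items()))
    win_start = window[0]
    return BarcodeAssignment(
        read_id,
        "assigned",
        barcode_id=bc_id,
        distance=dist,
        orientation=orientation,
        polyt=polyt,
        cp=cp_hit,
        barcode_locus=(win_start + locus[0], win_start + locus[1]),
    )


def _match_barcodes(
    oriented: str, window: tuple[int, int], barcodes: Mapping[str, str], max_dist: int
) -> dict[str, tuple[int, tuple[int, int]]]:
    target = oriented[window[0] : window[1]]
    hits: dict[str, tuple[int, tuple[int, int]]] = {}
    for bc_id, bc_seq in barcodes.items():
        hit = _best_infix(bc_seq, target, max_dist)
        if hit is not None:
            hits[bc_id] = (hit[2], (hit[0], hit[1]))
    return hits


def trim_read(read: str, assignment: BarcodeAssignment) -> str:
    """Remove barcode, poly-T and CP segments; return the insert in
    transcript sense (the oriented read between poly-T and CP is the
    reverse complement of the cDNA). Unassigned reads come back unchanged
    with ``trimmed_ok`` left False."""
    if assignment.status != "assigned":
        assignment.trimmed = read
        assignment.trimmed_ok = False
        return read
    oriented = read if assignment.orientation == "forward" else revcomp(read)
    left = 0
    if assignment.barcode_locus is not None:
        left = max(left, assignment.barcode_locus[1])
    if assignment.polyt is not None:
        left = max(left, assignment.polyt.end)
    right = len(oriented)
    if assignment.cp is not None:
        right = min(right, assignment.cp.start)
    right = max(right, left)
    insert = oriented[left:right]
    trimmed = revcomp(insert)
    assignment.trimmed = trimmed
    assignment.trimmed_ok = True
    return trimmed


def demux_reads(
    reads: Iterable[tuple[str, str]],
    barcodes: Mapping[str, str],
    cp: str | None = None,
    max_dist: int = DEFAULT_MAX_DIST,
    min_polyt: int = DEFAULT_MIN_POLYT,
) -> list[BarcodeAssignment]:
    """Demultiplex (read_id, sequence) pairs; every read receives a status."""
    out = []
    for rid, seq in reads:
        a = assign_barcode(rid, seq, barcodes, cp=cp, max_dist=max_dist, min_polyt=min_polyt)
        trim_read(seq, a)
        out.append(a)
    return out


def demux_report(assignments: Sequence[BarcodeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "status": a.status,
                "barcode_id": a.barcode_id,
                "distance": a.distance,
                "orientation": a.orientation,
                "reason": a.reason,
            }
            for a in assignments
        ]
    )


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_demuxed_fastq(
    assignments: Sequence[BarcodeAssignment],
    barcode_to_sample: Mapping[str, str],
    outdir: str | Path,
) -> dict[str, Path]:
    """One FASTQ of trimmed inserts per sample."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handles: dict[str, list[str]] = {s: [] for s in barcode_to_sample.values()}
    for a in assignments:
        if a.status != "assigned" or a.barcode_id not in barcode_to_sample:
            continue
        s = barcode_to_sample[a.barcode_id]
        handles[s].append(f"@{a.read_id}\n{a.trimmed}\n+\n{'I' * len(a.trimmed)}\n")
    paths = {}
    for s, chunks in handles.items():
        p = outdir / f"{s}.fastq"
        p.write_text("".join(chunks))
        paths[s] = p
    return paths
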