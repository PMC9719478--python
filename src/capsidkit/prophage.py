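"""Prophage locus calling, dif-site detection and conservation profiling.

Integrated phage-like elements of this family are recognizable by their
gene synteny — a replication-initiator gene followed closely by a major
capsid protein (MCP) gene — and by 28-nt palindromic dif sites (XerC
arm, central hexanucleotide, XerD arm) flanking both ends of the
integrated element, the signature of XerC/XerD-mediated integration at
the host's chromosome-dimer-resolution locus.

Homology hits are *inputs* (e.g. parsed BLASTp tables); this module never
runs a search.  Coordinates are 1-based inclusive throughout, on the
linearized sequence for circular genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HitRecord",
    "DifGeometry",
    "DifMotif",
    "ProphageLocus",
    "ConservationProfile",
    "call_prophage_loci",
    "palindrome_score",
    "find_dif_sites",
    "attach_dif_sites",
    "conservation_profile",
    "map_conservation_to_model",
    "logo_matrix",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class HitRecord:
    """One protein-homology hit located on a genome (1-based inclusive)."""

    query_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    score: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("hit start must be <= end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class DifGeometry:
    """Partition of the dif site into XerC arm, central spacer, XerD arm.

    The canonical bacterial dif architecture is 11 + 6 + 11 nt; the total
    site length considered here is 28 nt and the partition is
    configurable because reported sites differ in how flanking
    nucleotides are attributed to the arms.
    """

    xerc_arm: int = 11
    spacer: int = 6
    xerd_arm: int = 11

    @property
    def length(self) -> int:
        return self.xerc_arm + self.spacer + self.xerd_arm

    @property
    def spacer_range(self) -> tuple:
        return (self.xerc_arm, self.spacer)


@dataclass(frozen=True)
class DifMotif:
    position: int  # 1-based start on the genome
    sequence: str
    xerC_arm: str
    central_hexamer: str
    xerD_arm: str
    palindrome_score: float


@dataclass
class ProphageLocus:
    genome_id: str
    start: int
    end: int
    rep_hit: HitRecord
    mcp_hit: HitRecord
    strand: str = "+"
    dif_upstream: DifMotif | None = None
    dif_downstream: DifMotif | None = None
    length_flag: str = ""  # "", "short" or "long" vs the expected size range

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ConservationProfile:
    scores: np.ndarray  # per alignment column, z-score units
    column_map: dict  # alignment column (0-based) -> reference residue (1-based)


def call_prophage_loci(
    hits: list,
    max_gap: int = 10000,
    length_range: tuple = (5000, 10000),
) -> list:
    """Call prophage loci from rep-initiator + MCP homology hit pairs.

    A locus is one (rep, mcp) pair on the same genome and strand with the
    MCP gene following the rep gene in reading orientation within
    ``max_gap`` nt.  Overlapping pairings are resolved greedily by
    smallest gap, then leftmost coordinate, so the result is
    deterministic and input-order independent.  Provisional boundaries
    are the hit extents; loci outside ``length_range`` are flagged
    ("short"/"long"), never dropped.
    """
    by_genome: dict = {}
    for h in hits:
        by_genome.setdefault(h.genome_id, []).append(h)
    loci = []
    for genome_id in sorted(by_genome):
        reps = sorted(
            (h for h in by_genome[genome_id] if h.query_id == "rep_initiator"),
            key=lambda h: h.start,
        )
        mcps = sorted(
            (h for h in by_genome[genome_id] if h.query_id == "mcp"),
            key=lambda h: h.start,
        )
        candidates = []
        for r in reps:
            for m in mcps:
                if m.strand != r.strand:
                    continue
                gap = m.start - r.end - 1 if r.strand == "+" else r.start - m.end - 1
                if 0 <= gap <= max_gap:
                    candidates.append((gap, min(r.start, m.start), r, m))
        used: set = set()
        for gap, left, r, m in sorted(candidates, key=lambda c: (c[0], c[1])):
            if r in used or m in used:
                continue
            used.update((r, m))
            start = min(r.start, m.start)
            end = max(r.end, m.end)
            locus = ProphageLocus(
                genome_id=genome_id, start=start, end=end, rep_hit=r, mcp_hit=m, strand=r.strand
            )
            lo, hi = length_range
            if locus.length < lo:
                locus.length_flag = "short"
            elif locus.length > hi:
                locus.length_flag = "long"
            loci.append(locus)
    return sorted(loci, key=lambda l: (l.genome_id, l.start))


def palindrome_score(seq: str, spacer: tuple | None = None) -> float:
    """Fraction of non-spacer positions that base-pair with their mirror.

    Position i (0-based) pairs with position L-1-i; ambiguity codes count
    as mismatches.  ``spacer`` is a (start, length) range (0-based)
    excluded from scoring, e.g. the central hexanucleotide of a dif site.
    The score is invariant under reverse complement.
    """
    seq = seq.upper()
    L = len(seq)
    excluded = set()
    if spacer is not None:
        s, ln = spacer
        if s + ln > L:
            raise ValueError("spacer extends past the sequence")
        excluded = set(range(s, s + ln))
    scored = matched = 0
    for i in range(L):
        if i in excluded:
            continue
        scored += 1
        if _COMPLEMENT.get(seq[i]) == seq[L - 1 - i]:
            matched += 1
    if scored == 0:
        raise ValueError("no scorable positions")
    return matched / scored


def _motif_at(genome: str, pos0: int, geometry: DifGeometry) -> DifMotif:
    s = genome[pos0 : pos0 + geometry.length]
    return DifMotif(
        position=pos0 + 1,
        sequence=s,
        xerC_arm=s[: geometry.xerc_arm],
        central_hexamer=s[geometry.xerc_arm : geometry.xerc_arm + geometry.spacer],
        xerD_arm=s[geometry.xerc_arm + geometry.spacer :],
        palindrome_score=palindrome_score(s, spacer=geometry.spacer_range),
    )


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def find_dif_sites(
    genome: str,
    locus: ProphageLocus,
    flank: int = 5000,
    min_score: float = 0.8,
    min_pair_identity: float = 0.8,
    geometry: DifGeometry = DifGeometry(),
):
    """Scan a locus's flanks for a matched pair of palindromic dif sites.

    Both flanks are scanned for windows of the configured length whose
    palindrome score (spacer excluded) reaches ``min_score``; of the
    candidate pairs with sequence identity >= ``min_pair_identity``, the
    pair maximizing summed palindrome score (ties: closest to the locus)
    is returned.  Returns (None, None) when no acceptable pair exists --
    absence is a valid result, not an error.
    """
    L = geometry.length
    g = genome.upper()
    up_lo = max(0, locus.start - 1 - flank)
    up_hi = locus.start - 1 - L  # 0-based start of last window fully upstream
    down_lo = locus.end
    down_hi = min(len(g), locus.end + flank) - L

    def scan(lo, hi):
        # vectorized window palindrome scoring over the flank
        if hi < lo:
            return []
        region = g[lo : hi + L]
        if len(region) < L:
            return []
        codes = np.frombuffer(region.encode("ascii"), dtype=np.uint8)
        comp = np.zeros(256, dtype=np.uint8)
        for a, b in _COMPLEMENT.items():
            comp[ord(a)] = ord(b)
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)[: hi - lo + 1]
        s, ln = geometry.spacer_range
        keep = np.array([i for i in range(L) if not s <= i < s + ln])
        match = windows[:, keep] == comp[windows[:, L - 1 - keep]]
        scores = match.mean(axis=1)
        return [(lo + int(i), float(scores[i])) for i in np.nonzero(scores >= min_score)[0]]

    ups = scan(up_lo, up_hi)
    downs = scan(down_lo, down_hi)
    best = None
    for pu, su in ups:
        for pd, sd in downs:
            if _identity(g[pu : pu + L], g[pd : pd + L]) < min_pair_identity:
                continue
            # prefer high palindromicity, then the tightest bracketing
            rank = (-(su + sd), (locus.start - 1 - pu) + (pd - locus.end))
            if best is None or rank < best[0]:
                best = (rank, pu, pd)
    if best is None:
        return None, None
    _, pu, pd = best
    return _motif_at(g, pu, geometry), _motif_at(g, pd, geometry)


def attach_dif_sites(
    genome: str, locus: ProphageLocus, max_length: int = 10000, **kwargs
) -> ProphageLocus:
    """Refine a locus with its dif pair: boundaries snap to the inner dif edges.

    The scan flank defaults to whatever would let the dif pair bracket a
    prophage of up to ``max_length`` nt around the provisional hit
    extents, since homology hits cover only the rep/MCP genes, not the
    whole element.
    """
    kwargs.setdefault("flank", max(5000, max_length - locus.length))
    up, down = find_dif_sites(genome, locus, **kwargs)
    if up is None:
        return locus
    geometry = kwargs.get("geometry", DifGeometry())
    return replace(
        locus,
        dif_upstream=up,
        dif_downstream=down,
        start=up.position + geometry.length,
        end=down.position - 1,
    )


def _rows_from_msa(msa) -> list:
    """Accept a Bio.Align alignment, SeqRecords, (id, seq) pairs or strings."""
    rows = []
    for i, rec in enumerate(msa):
        rid = getattr(rec, "id", None)
        seq = getattr(rec, "seq", rec)
        if rid is None and isinstance(rec, tuple):
            rid, seq = rec
        rows.append((rid if rid is not None else f"seq{i}", str(seq).upper()))
    if len(rows) < 2:
        raise ValueError("alignment needs at least two sequences")
    if len({len(s) for _, s in rows}) != 1:
        raise ValueError("alignment rows differ in length")
    return rows


def conservation_profile(msa, reference_row: str) -> ConservationProfile:
    """Per-column conservation of an alignment, z-normalized.

    The raw per-column score is the sum-of-pairs identity over non-gap
    residue pairs (columns whose non-gap pairs all agree score 1).  Raw
    scores are z-normalized across columns, matching the signed score
    ranges conventional for conservation coloring; a zero-variance
    alignment maps to all-zero scores.  ``column_map`` indexes the
    columns where the reference row is ungapped by reference residue
    number (1-based).
    """
    rows = _rows_from_msa(msa)
    ids = [r for r, _ in rows]
    if reference_row not in ids:
        raise ValueError(f"reference row {reference_row!r} not in alignment")
    seqs = [s for _, s in rows]
    ncol = len(seqs[0])
    raw = np.zeros(ncol)
    for c in range(ncol):
        col = [s[c] for s in seqs if s[c] not in "-."]
        if len(col) < 2:
            raw[c] = 0.0
            continue
        pairs = same = 0
        for i in range(len(col)):
            for j in range(i + 1, len(col)):
                pairs += 1
                same += col[i] == col[j]
        raw[c] = same / pairs
    sd = raw.std()
    scores = (raw - raw.mean()) / sd if sd > 1e-12 else np.zeros(ncol)
    ref = seqs[ids.index(reference_row)]
    column_map = {}
    resno = 0
    for c, ch in enumerate(ref):
        if ch not in "-.":
            resno += 1
            column_map[c] = resno
    return ConservationProfile(scores=scores, column_map=column_map)


#: B-factor sentinel for residues absent from the profile's column map.
UNMAPPED_BFACTOR = -9.99


def map_conservation_to_model(
    profile: ConservationProfile, coords_path, chain: str, out_path
) -> int:
    """Write per-residue conservation into a PDB file's B-factor column.

    Residue numbers in ``chain`` are matched against the profile's
    reference numbering; atoms of unmapped residues get the sentinel
    -9.99.  Returns the number of residues that received a score.
    """
    import gemmi

    structure = gemmi.read_structure(str(coords_path))
    by_residue = {res: float(profile.scores[c]) for c, res in profile.column_map.items()}
    mapped = 0
    found_chain = False
    for model in structure:
        for ch in model:
            if ch.name != chain:
                continue
            found_chain = True
            for residue in ch:
                score = by_residue.get(residue.seqid.num)
                if score is not None:
                    mapped += 1
                for atom in residue:
                    atom.b_iso = UNMAPPED_BFACTOR if score is None else score
    if not found_chain:
        raise ValueError(f"chain {chain!r} not found in {coords_path}")
    structure.setup_entities()
    doc = structure.make_pdb_string()
    with open(out_path, "w") as fh:
        fh.write(f"REMARK   3 B-FACTOR = CONSERVATION Z-SCORE; UNMAPPED = {UNMAPPED_BFACTOR}\n")
        fh.write(doc)
    return mapped


def logo_matrix(motifs: list):
    """Position frequency matrix and per-column information content.

    Information content is 2 - H bits per column (Shannon entropy over
    the observed A/C/G/T frequencies, 0 log 0 = 0); the small-sample
    correction is off, matching the plain WebLogo definition.
    Returns ``(freq, info)`` where freq has shape (L, 4) in A, C, G, T
    order.
    """
    if len(motifs) < 2:
        raise ValueError("need at least two motif sequences")
    L = len(motifs[0])
    if any(len(m) != L for m in motifs):
        raise ValueError("motif sequences differ in length")
    order = "ACGT"
    counts = np.zeros((L, 4))
    for m in motifs:
        for i, ch in enumerate(m.upper()):
            if ch in order:
                counts[i, order.index(ch)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freq = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return freq, info
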