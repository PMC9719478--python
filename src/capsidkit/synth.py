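"""Seeded synthetic-data generators for every pipeline stage.

Each generator takes an explicit integer seed and draws from a single
``numpy.random.default_rng`` stream, so regeneration with the same seed
is bit-identical.  Defaults emulate the study conditions: particle tables
with defocus 0.1-2.2 um at 1.24 A/pixel, a circular 7642-nt phage
cassette at 30.5% GC carrying rep-initiator, MCP and spike ORFs flanked
by 28-nt dif palindromes, and mutated cassette families for conservation
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .localrec import ParticleRecord
from .prophage import HitRecord

__all__ = [
    "SyntheticParticleSet",
    "SyntheticGenome",
    "SyntheticFamily",
    "gen_particle_table",
    "gen_genome",
    "implant_prophage",
    "mutate_family",
    "DEFAULT_DIF",
]

_BASES = np.array(list("ACGT"))

#: 28-nt dif-like site: 11-nt XerC arm + central hexanucleotide + 11-nt XerD
#: arm, built as a perfect palindrome so implanted copies score 1.0.
DEFAULT_DIF = "ACGTTCGATAACTTATGTTATCGAACGT"


@dataclass
class SyntheticParticleSet:
    particles: list
    seed: int
    n: int
    defocus_range: tuple  # um
    orientation_model: str = "uniform-SO3"


@dataclass
class SyntheticGenome:
    sequence: str
    gc: float
    circular: bool
    truth: list = field(default_factory=list)  # feature dicts with exact coordinates
    seed: int = 0

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def truth_hits(self) -> list:
        return [f["hit"] for f in self.truth if "hit" in f]


@dataclass
class SyntheticFamily:
    sequences: list
    sub_rate: float
    indel_rate: float
    truth_alignment: list  # aligned rows, same length, '-' gaps
    site_weights: np.ndarray  # per-cassette-site substitution weight
    seed: int = 0


def gen_particle_table(
    n: int,
    seed: int,
    defocus_range: tuple = (0.1, 2.2),
    pixel_size: float = 1.24,
) -> SyntheticParticleSet:
    """n particle records with uniform orientations and uniform defoci.

    Orientations are drawn uniformly over rotations via normalized
    Gaussian quaternions; defoci (u = v, astigmatism-free) are uniform
    over ``defocus_range`` in micrometres and stored in Angstrom.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = defocus_range
    if not hi > lo:
        raise ValueError("empty defocus range")
    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    eulers = Rotation.from_quat(quats).as_euler("ZYZ", degrees=True)
    defoci = rng.uniform(lo, hi, size=n) * 1e4  # um -> Angstrom
    origins = rng.uniform(-2.0, 2.0, size=(n, 2))
    particles = [
        ParticleRecord(
            id=f"p{i:06d}",
            euler_rot=float(eulers[i, 0]),
            euler_tilt=float(eulers[i, 1]),
            euler_psi=float(eulers[i, 2]),
            origin_x=float(origins[i, 0]),
            origin_y=float(origins[i, 1]),
            defocus_u=float(defoci[i]),
            defocus_v=float(defoci[i]),
            image_ref=f"{i + 1:06d}@particles.mrcs",
            pixel_size=pixel_size,
        )
        for i in range(n)
    ]
    return SyntheticParticleSet(
        particles=particles, seed=seed, n=n, defocus_range=tuple(defocus_range)
    )


def gen_genome(length: int, gc: float, circular: bool, seed: int) -> SyntheticGenome:
    """Random genome with i.i.d. bases at the requested GC content."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return SyntheticGenome(sequence=seq, gc=gc, circular=circular, seed=seed)


def _synthetic_orf(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def build_cassette(
    cassette_length: int = 7642,
    gc: float = 0.305,
    dif_seq: str = DEFAULT_DIF,
    seed: int = 0,
):
    """A prophage-like cassette: rep, MCP and spike ORFs, dif sites outside.

    Returns ``(sequence, features)`` where features give 1-based inclusive
    coordinates of each ORF within the cassette.  The gene order mirrors
    the shared synteny of the phage family: replication initiator near
    the start, followed by the major capsid protein, then the spike.
    """
    if len(dif_seq) != 28:
        raise ValueError(f"dif site must be 28 nt, got {len(dif_seq)}")
    rng = np.random.default_rng(seed)
    # ORF lengths loosely modelled on the phage: rep ~1 kb, MCP 720 nt
    # (239 aa + stop), spike 852 nt (283 aa + stop)
    orf_lengths = {"rep_initiator": 999, "mcp": 720, "spike": 852}
    # rep near the start, MCP close behind, spike near the end (the
    # family's shared synteny); the spike gap absorbs the remaining length
    spike_gap = cassette_length - 200 - 852 - (150 + 999 + 120 + 720)
    gaps = [150, 120, spike_gap if spike_gap > 0 else 130]
    pieces = []
    features = []
    pos = 0
    for (name, ln), gap in zip(orf_lengths.items(), gaps):
        spacer = _synthetic_orf(rng, gap, gc)
        pieces.append(spacer)
        pos += gap
        orf = _synthetic_orf(rng, ln, gc)
        pieces.append(orf)
        features.append({"name": name, "start": pos + 1, "end": pos + ln, "strand": "+"})
        pos += ln
    tail = cassette_length - pos
    if tail < 0:
        raise ValueError("cassette_length too small for the three ORFs")
    pieces.append(_synthetic_orf(rng, tail, gc))
    return "".join(pieces), features


def implant_prophage(
    host: SyntheticGenome,
    cassette_length: int = 7642,
    dif_seq: str = DEFAULT_DIF,
    position=None,
    seed: int = 0,
) -> SyntheticGenome:
    """Insert a dif-flanked prophage cassette into a host genome.

    The cassette (rep -> MCP -> spike) is inserted at ``position``
    (0-based insertion point; random when None) with one copy of
    ``dif_seq`` immediately upstream and one immediately downstream.
    The returned genome's truth records carry exact 1-based coordinates
    of the locus, ORFs and dif sites, plus synthetic homology HitRecords
    for the rep and MCP genes (the inputs a prophage scan consumes).
    """
    if len(dif_seq) != 28:
        raise ValueError(f"dif site must be 28 nt, got {len(dif_seq)}")
    rng = np.random.default_rng(seed)
    insert_len = cassette_length + 2 * len(dif_seq)
    if insert_len > len(host.sequence):
        raise ValueError("cassette does not fit in the host genome")
    if position is None:
        position = int(rng.integers(0, len(host.sequence)))
    if not 0 <= position <= len(host.sequence):
        raise ValueError("position out of range")
    cassette, orfs = build_cassette(
        cassette_length=cassette_length, gc=host.gc, dif_seq=dif_seq, seed=seed
    )
    new_seq = (
        host.sequence[:position] + dif_seq + cassette + dif_seq + host.sequence[position:]
    )
    locus_start = position + len(dif_seq) + 1  # 1-based, cassette proper
    locus_end = locus_start + cassette_length - 1
    genome_id = "synthetic_host"
    truth = [
        {
            "feature": "prophage",
            "start": locus_start,
            "end": locus_end,
            "dif_upstream": position + 1,
            "dif_downstream": locus_end + 1,
            "dif_seq": dif_seq,
        }
    ]
    for orf in orfs:
        start = locus_start + orf["start"] - 1
        end = locus_start + orf["end"] - 1
        entry = {
            "feature": orf["name"],
            "start": start,
            "end": end,
            "strand": orf["strand"],
        }
        if orf["name"] in ("rep_initiator", "mcp"):
            entry["hit"] = HitRecord(
                query_id=orf["name"],
                genome_id=genome_id,
                start=start,
                end=end,
                strand=orf["strand"],
                score=100.0,
            )
        truth.append(entry)
    return SyntheticGenome(
        sequence=new_seq, gc=host.gc, circular=host.circular, truth=truth, seed=seed
    )


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def mutate_family(
    cassette: str,
    n: int,
    sub_rate: float,
    indel_rate: float,
    seed: int,
    weight_concentration: float | None = None,
) -> SyntheticFamily:
    """n mutated copies of a cassette with truth alignment bookkeeping.

    Substitutions are Jukes-Cantor-like (uniform over the three other
    bases) at per-site probability ``sub_rate * w_i`` where the optional
    per-site weights ``w_i`` (mean 1, gamma-distributed when
    ``weight_concentration`` is given) emulate site-specific conservation;
    indels start at per-site probability ``indel_rate`` with geometric
    lengths (mean 3).  The truth alignment keeps one column per ancestral
    site plus insertion columns, so per-column variability can be compared
    against the generating weights.
    """
    if not (0.0 <= sub_rate < 0.5 and 0.0 <= indel_rate < 0.5):
        raise ValueError("rates must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    L = len(cassette)
    if weight_concentration:
        weights = rng.gamma(weight_concentration, 1.0 / weight_concentration, size=L)
    else:
        weights = np.ones(L)
    site_p = np.clip(sub_rate * weights, 0.0, 0.95)

    # per row: list of per-ancestral-site strings ('' = deletion, base,
    # or base + insertion suffix); insertions recorded per (row, site)
    rows = []
    insert_len = np.zeros(L + 1, dtype=int)  # max insertion length after site i
    per_row_inserts = []
    for _ in range(n):
        sub_mask = rng.random(L) < site_p
        cells = list(cassette)
        for i in np.nonzero(sub_mask)[0]:
            others = [b for b in "ACGT" if b != cassette[i]]
            cells[i] = others[rng.integers(0, 3)]
        dels = rng.random(L) < indel_rate / 2.0
        for i in np.nonzero(dels)[0]:
            cells[i] = ""
        inserts = {}
        ins_mask = rng.random(L + 1) < indel_rate / 2.0
        for i in np.nonzero(ins_mask)[0]:
            ln = int(rng.geometric(1.0 / 3.0))
            inserts[i] = "".join(rng.choice(_BASES, size=ln))
            insert_len[i] = max(insert_len[i], ln)
        rows.append(cells)
        per_row_inserts.append(inserts)

    aligned = []
    sequences = []
    for cells, inserts in zip(rows, per_row_inserts):
        parts = []
        for i in range(L + 1):
            ins = inserts.get(i, "")
            parts.append(ins + "-" * (insert_len[i] - len(ins)))
            if i < L:
                parts.append(cells[i] if cells[i] else "-")
        row = "".join(parts)
        aligned.append(row)
        sequences.append(row.replace("-", ""))
    return SyntheticFamily(
        sequences=sequences,
        sub_rate=sub_rate,
        indel_rate=indel_rate,
        truth_alignment=aligned,
        site_weights=weights,
        seed=seed,
    )
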