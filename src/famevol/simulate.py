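"""Synthetic genomes with planted ground truth for pipeline benchmarking.

Generates chromosomes of ordered background genes carrying a gene family
with two planted catalytic HKD motifs per member, single-HKD decoys, one
premature-stop pseudogene, tandem pairs at adjacent ranks, segmental
pairs on different chromosomes with partially conserved flanking blocks,
and coding-sequence pairs evolved to a chosen synonymous distance.  All
randomness flows from one config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .family import scan_hkd, _separated_hits
from .kaks import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, ng86_site_counts

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "GenomeBundle",
    "evolve_cds_pair",
    "simulate_genome",
    "write_bundle",
]

_BASES = "ACGT"

#: amino acid -> sense codons (standard code)
_AA_CODONS: dict[str, list[str]] = {}
for _codon, _aa in GENETIC_CODE.items():
    if _aa != "*":
        _AA_CODONS.setdefault(_aa, []).append(_codon)
for _v in _AA_CODONS.values():
    _v.sort()


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 4
    genes_per_chromosome: int = 80
    n_family_members: int = 10
    n_tandem_pairs: int = 1
    n_segmental_pairs: int = 2
    flank_window: int = 10
    flank_retention: float = 0.5
    target_ks: float = 0.25
    omega: float = 0.2
    codons_per_gene: int = 300
    n_decoys: int = 2
    n_pseudogenes: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.flank_retention <= 1.0:
            raise ConfigError("flank_retention must be in [0, 1]")
        if self.target_ks < 0 or self.omega < 0:
            raise ConfigError("target_ks and omega must be non-negative")
        for name in (
            "n_chromosomes",
            "genes_per_chromosome",
            "n_family_members",
            "n_tandem_pairs",
            "n_segmental_pairs",
            "flank_window",
            "codons_per_gene",
            "n_decoys",
            "n_pseudogenes",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if 2 * (self.n_tandem_pairs + self.n_segmental_pairs) > self.n_family_members:
            raise ConfigError("more paired genes requested than family members")
        if self.n_segmental_pairs and self.n_chromosomes < 2:
            raise ConfigError("segmental pairs need at least 2 chromosomes")
        if self.codons_per_gene < 80:
            raise ConfigError("codons_per_gene must be >= 80 to host the planted motifs")


@dataclass
class PlantedPair:
    gene1: str
    gene2: str
    mechanism: str  # tandem | segmental
    true_flank_count: Optional[int]
    target_ks: float
    omega: float


@dataclass
class GroundTruth:
    genes: dict[str, dict]  # id -> {member, subfamily, pseudogene, species}
    pairs: list[PlantedPair]

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "pairs": [asdict(p) for p in self.pairs],
        }


@dataclass
class GenomeBundle:
    proteins: dict[str, str]
    cds: dict[str, str]
    alignment_ids: tuple[str, ...]
    alignment_rows: tuple[str, ...]
    loci: list[tuple[str, str, int, int, str]]  # gene_id, chrom, start, end, strand
    homology: list[tuple[str, str]]
    domains: list[tuple[str, str, int, int]]
    motif_defs: list[tuple[str, str]]
    species: str
    truth: GroundTruth


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _neighbors(codon: str, synonymous: bool) -> list[str]:
    """Non-stop single-base mutants of the requested class, sorted."""
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            if (GENETIC_CODE[mut] == aa) == synonymous:
                out.append(mut)
    return sorted(out)


def _evolve_branch(
    codons: list[str],
    n_syn: int,
    n_non: int,
    rng: np.random.Generator,
    frozen: frozenset,
    max_retries: int = 1000,
) -> list[str]:
    seq = list(codons)
    s_arr = np.zeros(len(seq))
    n_arr = np.zeros(len(seq))
    for i, c in enumerate(seq):
        if i in frozen:
            continue
        s_arr[i], n_arr[i] = ng86_site_counts(c)
    kinds = np.array([0] * n_syn + [1] * n_non)
    rng.shuffle(kinds)
    for kind in kinds:
        synonymous = kind == 0
        weights = s_arr if synonymous else n_arr
        placed = False
        for _ in range(max_retries):
            total = weights.sum()
            if total <= 0:
                break
            idx = rng.choice(len(seq), p=weights / total)
            options = _neighbors(seq[idx], synonymous)
            if not options:
                weights[idx] = 0.0  # no viable neighbor despite fractional sites
                continue
            seq[idx] = options[rng.integers(len(options))]
            s_arr[idx], n_arr[idx] = ng86_site_counts(seq[idx])
            placed = True
            break
        if not placed:
            raise RuntimeError("no viable site left for a drawn substitution event")
    return seq


def evolve_cds_pair(
    ancestral_cds: str,
    target_ks: float,
    omega: float,
    seed: int,
    frozen_codons: Iterable[int] = (),
) -> tuple[str, str]:
    """Evolve two descendant CDSs to an expected synonymous distance.

    Each lineage draws a Poisson number of synonymous events with mean
    ``target_ks/2`` per synonymous site (sites counted as in NG86) and of
    nonsynonymous events with mean ``omega * target_ks/2`` per
    nonsynonymous site; events land on codons weighted by their current
    fractional site counts and pick uniformly among single-base neighbors
    of the required class, never creating stops.  ``frozen_codons`` (0-based
    indices) are exempt from mutation.  Deterministic given seed.
    """
    cds = ancestral_cds.upper()
    if len(cds) % 3:
        raise ValueError("ancestral CDS length must be a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("ancestral CDS contains a stop codon")
    if target_ks < 0 or omega < 0:
        raise ValueError("target_ks and omega must be non-negative")
    frozen = frozenset(frozen_codons)
    S = N = 0.0
    for i, c in enumerate(codons):
        if i in frozen:
            continue
        s, n = ng86_site_counts(c)
        S += s
        N += n
    out = []
    for branch in range(2):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(branch,)))
        n_syn = int(rng.poisson(target_ks / 2.0 * S)) if target_ks > 0 else 0
        n_non = int(rng.poisson(omega * target_ks / 2.0 * N)) if omega * target_ks > 0 else 0
        out.append("".join(_evolve_branch(codons, n_syn, n_non, rng, frozen)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n)]


def _encode(rng: np.random.Generator, residues: str) -> list[str]:
    return [
        _AA_CODONS[aa][rng.integers(len(_AA_CODONS[aa]))]
        for aa in residues
    ]


def _plant(codons: list[str], pos: int, planted: list[str]) -> None:
    codons[pos : pos + len(planted)] = planted


def _translate_codons(codons: list[str]) -> str:
    return "".join(GENETIC_CODE[c] for c in codons)


def _family_ancestor(rng: np.random.Generator, n_codons: int) -> tuple[list[str], list[int]]:
    """Random CDS carrying two HKD motifs and the IYIENQFF motif.

    Returns (codons, frozen anchor codon indices) where the anchors are
    the H/K/D residues of both motifs, kept immune to mutation so planted
    members always stay detectable.
    """
    h1 = n_codons // 3
    h2 = (2 * n_codons) // 3
    m3 = n_codons // 6
    codons = _random_codons(rng, n_codons)
    _plant(codons, m3, _encode(rng, "IYIENQFF"))
    for h in (h1, h2):
        _plant(codons, h, _encode(rng, "H"))
        _plant(codons, h + 2, _encode(rng, "K"))
        _plant(codons, h + 7, _encode(rng, "D"))
    frozen = [h1, h1 + 2, h1 + 7, h2, h2 + 2, h2 + 7]
    return codons, frozen


def _decoy_cds(rng: np.random.Generator, n_codons: int, max_tries: int = 200) -> list[str]:
    """CDS whose protein carries exactly one qualifying HKD region."""
    for _ in range(max_tries):
        codons = _random_codons(rng, n_codons)
        h = n_codons // 2
        _plant(codons, h, _encode(rng, "H"))
        _plant(codons, h + 2, _encode(rng, "K"))
        _plant(codons, h + 7, _encode(rng, "D"))
        hits = _separated_hits(scan_hkd(_translate_codons(codons)), 50)
        if len(hits) == 1:
            return codons
    raise RuntimeError("failed to construct a single-HKD decoy")


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _placement_positions(cfg: SimulationConfig) -> list[int]:
    """Insertion offsets into a chromosome's background list, well spaced."""
    spacing = 2 * cfg.flank_window + 2
    lo = cfg.flank_window
    hi = cfg.genes_per_chromosome - cfg.flank_window
    return list(range(lo, hi + 1, spacing))


def simulate_genome(config: SimulationConfig) -> GenomeBundle:
    """Build a full synthetic bundle with ground truth; see module docstring."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,)))
    species = "Simulated"

    n_paired = 2 * (cfg.n_tandem_pairs + cfg.n_segmental_pairs)
    n_singletons = cfg.n_family_members - n_paired
    member_ids = [f"FAM{k:02d}" for k in range(1, cfg.n_family_members + 1)]
    decoy_ids = [f"DECOY{k}" for k in range(1, cfg.n_decoys + 1)]
    pseudo_ids = [f"PSG{k}" for k in range(1, cfg.n_pseudogenes + 1)]

    # --- units to place: (unit_genes, kind) ---
    tandem_pairs = []
    segmental_pairs = []
    cursor = 0
    for _ in range(cfg.n_tandem_pairs):
        tandem_pairs.append((member_ids[cursor], member_ids[cursor + 1]))
        cursor += 2
    for _ in range(cfg.n_segmental_pairs):
        segmental_pairs.append((member_ids[cursor], member_ids[cursor + 1]))
        cursor += 2
    singleton_ids = member_ids[cursor:]

    units: list[tuple[list[str], Optional[str]]] = []  # (genes, forced_chromosome)
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chromosomes)]
    chrom_cycle = 0

    def next_chrom(avoid: Optional[str] = None) -> str:
        nonlocal chrom_cycle
        for _ in range(cfg.n_chromosomes):
            name = chrom_names[chrom_cycle % cfg.n_chromosomes]
            chrom_cycle += 1
            if name != avoid:
                return name
        raise ConfigError("cannot pick a distinct chromosome")

    placements: dict[str, list[list[str]]] = {c: [] for c in chrom_names}
    for pair in tandem_pairs:
        placements[next_chrom()].append(list(pair))
    for g1, g2 in segmental_pairs:
        c1 = next_chrom()
        placements[c1].append([g1])
        placements[next_chrom(avoid=c1)].append([g2])
    for gid in singleton_ids + decoy_ids + pseudo_ids:
        placements[next_chrom()].append([gid])

    positions = _placement_positions(cfg)
    for chrom, chrom_units in placements.items():
        if len(chrom_units) > len(positions):
            raise ConfigError(
                f"infeasible placement: {len(chrom_units)} family units on {chrom} "
                f"but only {len(positions)} well-spaced slots "
                f"(increase genes_per_chromosome or n_chromosomes)"
            )

    # --- final gene order per chromosome ---
    order: dict[str, list[str]] = {}
    for ci, chrom in enumerate(chrom_names):
        background = [f"BG{ci + 1}g{j:03d}" for j in range(cfg.genes_per_chromosome)]
        inserts = sorted(
            zip(positions[: len(placements[chrom])], placements[chrom]),
            key=lambda t: -t[0],
        )
        for pos, genes in inserts:  # highest first keeps earlier offsets valid
            background[pos:pos] = genes
        order[chrom] = background

    loci: list[tuple[str, str, int, int, str]] = []
    for chrom in chrom_names:
        for idx, gid in enumerate(order[chrom]):
            start = 1 + idx * 2000
            loci.append((gid, chrom, start, start + 999, "+"))

    # --- homology among flanking genes of segmental pairs ---
    rank = {gid: (chrom, i) for chrom in chrom_names for i, gid in enumerate(order[chrom])}
    family_like = set(member_ids) | set(decoy_ids) | set(pseudo_ids)

    def background_flank(gid: str, step: int) -> list[str]:
        chrom, i = rank[gid]
        out = []
        j = i + step
        while 0 <= j < len(order[chrom]) and len(out) < cfg.flank_window:
            other = order[chrom][j]
            if other not in family_like:
                out.append(other)
            j += step
        return out

    homology: list[tuple[str, str]] = []
    truth_pairs: list[PlantedPair] = []
    flank_pair_targets: list[tuple[str, str, float]] = []
    for g1, g2 in segmental_pairs:
        count = 0
        for step in (-1, 1):
            fa = background_flank(g1, step)
            fb = background_flank(g2, step)
            for a, b in zip(fa, fb):
                if rng.random() < cfg.flank_retention:
                    homology.append((a, b))
                    flank_pair_targets.append((a, b, cfg.target_ks))
                    count += 1
        truth_pairs.append(
            PlantedPair(g1, g2, "segmental", count, cfg.target_ks, cfg.omega)
        )
    for g1, g2 in tandem_pairs:
        truth_pairs.append(PlantedPair(g1, g2, "tandem", None, cfg.target_ks, cfg.omega))

    # --- sequences ---
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    seq_seed = int(rng.integers(0, 2**31 - 1))
    for k, (g1, g2) in enumerate(tandem_pairs + segmental_pairs):
        anc, frozen = _family_ancestor(rng, cfg.codons_per_gene)
        c1, c2 = evolve_cds_pair(
            "".join(anc), cfg.target_ks, cfg.omega, seed=seq_seed + k, frozen_codons=frozen
        )
        cds[g1], cds[g2] = c1, c2
        proteins[g1] = _translate_codons([c1[i : i + 3] for i in range(0, len(c1), 3)])
        proteins[g2] = _translate_codons([c2[i : i + 3] for i in range(0, len(c2), 3)])
    for gid in singleton_ids:
        anc, _ = _family_ancestor(rng, cfg.codons_per_gene)
        cds[gid] = "".join(anc)
        proteins[gid] = _translate_codons(anc)
    for gid in decoy_ids:
        codons = _decoy_cds(rng, cfg.codons_per_gene)
        cds[gid] = "".join(codons)
        proteins[gid] = _translate_codons(codons)
    for gid in pseudo_ids:
        anc, _ = _family_ancestor(rng, cfg.codons_per_gene)
        anc[cfg.codons_per_gene - 5] = "TAA"  # premature in-frame stop
        cds[gid] = "".join(anc)
        proteins[gid] = _translate_codons(anc)

    # flanking background gene pairs get short CDSs evolved at the pair Ks
    for fk, (a, b, ks) in enumerate(flank_pair_targets):
        anc = _random_codons(rng, 120)
        c1, c2 = evolve_cds_pair("".join(anc), ks, cfg.omega, seed=seq_seed + 10_000 + fk)
        cds[a], cds[b] = c1, c2
        proteins[a] = _translate_codons([c1[i : i + 3] for i in range(0, len(c1), 3)])
        proteins[b] = _translate_codons([c2[i : i + 3] for i in range(0, len(c2), 3)])

    # --- alignment (members share one length: trivially aligned) ---
    aln_ids = tuple(sorted(set(member_ids)))
    aln_rows = tuple(proteins[g] for g in aln_ids)

    # --- domain annotations: pairs are C2; singletons cycle PXPH / SP / C2 ---
    domains: list[tuple[str, str, int, int]] = []
    subfamily: dict[str, str] = {}
    for g1, g2 in tandem_pairs + segmental_pairs:
        for g in (g1, g2):
            domains.append((g, "C2", 1, 120))
            subfamily[g] = "C2"
    cycle = ["PXPH", "SP", "C2"]
    for i, gid in enumerate(singleton_ids):
        kind = cycle[i % 3]
        subfamily[gid] = kind
        if kind == "C2":
            domains.append((gid, "C2", 1, 120))
        elif kind == "PXPH":
            domains.append((gid, "PX", 1, 100))
            domains.append((gid, "PH", 110, 210))
        else:
            domains.append((gid, "SignalPeptide", 1, 25))
    for gid in pseudo_ids:
        domains.append((gid, "C2", 1, 120))
        subfamily[gid] = "C2"

    genes_truth: dict[str, dict] = {}
    for gid in member_ids:
        genes_truth[gid] = {
            "member": True,
            "subfamily": subfamily[gid],
            "pseudogene": False,
            "species": species,
        }
    for gid in decoy_ids:
        genes_truth[gid] = {
            "member": False,
            "subfamily": "unclassified",
            "pseudogene": False,
            "species": species,
        }
    for gid in pseudo_ids:
        genes_truth[gid] = {
            "member": True,
            "subfamily": subfamily[gid],
            "pseudogene": True,
            "species": species,
        }

    motif_defs = [("3", "IYIENQ[FY]F"), ("HKD", "H.K....D")]

    return GenomeBundle(
        proteins=proteins,
        cds=cds,
        alignment_ids=aln_ids,
        alignment_rows=aln_rows,
        loci=loci,
        homology=homology,
        domains=domains,
        motif_defs=motif_defs,
        species=species,
        truth=GroundTruth(genes=genes_truth, pairs=truth_pairs),
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def _write_fasta(path: Path, records: dict[str, str]) -> None:
    with path.open("w") as fh:
        for gid in sorted(records):
            fh.write(f">{gid}\n{records[gid]}\n")


def write_bundle(bundle: GenomeBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files; byte-stable given the seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": directory / "proteins.faa",
        "cds": directory / "cds.fna",
        "alignment": directory / "alignment.faa",
        "genes": directory / "genes.gff3",
        "homology": directory / "homology.tsv",
        "domains": directory / "domains.tsv",
        "motifs": directory / "motifs.tsv",
        "truth": directory / "ground_truth.json",
    }
    _write_fasta(paths["proteins"], bundle.proteins)
    _write_fasta(paths["cds"], bundle.cds)
    with paths["alignment"].open("w") as fh:
        for gid, row in zip(bundle.alignment_ids, bundle.alignment_rows):
            fh.write(f">{gid}\n{row}\n")
    with paths["genes"].open("w") as fh:
        fh.write("##gff-version 3\n")
        for gid, chrom, start, end, strand in bundle.loci:
            fh.write(f"{chrom}\tfamevol\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}\n")
    with paths["homology"].open("w") as fh:
        fh.write("gene1\tgene2\n")
        for a, b in sorted(bundle.homology):
            fh.write(f"{a}\t{b}\n")
    with paths["domains"].open("w") as fh:
        fh.write("gene_id\tdomain\tstart\tend\n")
        for row in sorted(bundle.domains):
            fh.write("\t".join(map(str, row)) + "\n")
    with paths["motifs"].open("w") as fh:
        fh.write("motif_id\tpattern\n")
        for mid, pattern in bundle.motif_defs:
            fh.write(f"{mid}\t{pattern}\n")
    with paths["truth"].open("w") as fh:
        json.dump(bundle.truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
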