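"""Synthetic clades with known ground truth for every divergence layer.

A reference genome is evolved along independent branches to a set of
descendant species at stated divergence times (Myrs).  Three mutational
processes act on each branch:

* **segment loss** — contiguous blocks are deleted with an exponential
  per-Myr hazard that can differ between annotation classes (genic,
  promoter, accessible, inaccessible chromatin), so that the fraction of a
  class surviving after ``t`` Myrs is ``exp(-hazard * t)``;
* **indels** — small insertions/deletions (geometric lengths, capped) at a
  per-site-per-Myr event rate, splitting alignment blocks the way liftOver
  chains see them;
* **substitutions** — Poisson point substitutions at a per-site-per-Myr
  rate (multiple hits at one site allowed, so observed divergence shows the
  usual back-substitution deficit).

The surviving correspondence between reference and descendant is recorded
as a ground-truth UCSC-convention :class:`~netdecay.homology.ChainMap`
(optionally with inverted, minus-strand segments).  On top of the clade the
module simulates ChIP fragment read sets around (partially) conserved
binding sites, orthologous expression tables whose rank correlation decays
exponentially with time, and genomes with implanted motif matches.

All generators are deterministic given a :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .homology import Chain, ChainMap, revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

#: default per-Myr segment-loss hazards by annotation class; the
#: inaccessible-genome hazard 0.012 yields ~30% retention at 100 Myrs
#: (mammal-like) and 0.004 yields ~67% (bird/insect-like)
DEFAULT_LOSS_RATES = {
    "genic": 0.001,
    "promoter": 0.001,
    "accessible": 0.004,
    "inaccessible": 0.012,
}


@dataclass(frozen=True)
class EvolParams:
    """Branch-process rates of the genome evolution simulator.

    ``loss_rate`` is either one hazard for the whole genome or a mapping
    from annotation class to hazard (per Myr).  ``loss_block`` sets the
    granularity of segment loss in bp; losses never cross annotation-class
    boundaries.  Indel lengths are geometric(p) capped at ``indel_cap`` bp.
    """

    sub_rate: float = 0.002
    indel_rate: float = 0.0002
    indel_geom_p: float = 0.3
    indel_cap: int = 50
    loss_rate: float | dict = field(default_factory=lambda: dict(DEFAULT_LOSS_RATES))
    loss_block: int = 2500
    inversion_rate: float = 0.0

    def __post_init__(self) -> None:
        rates = (
            list(self.loss_rate.values())
            if isinstance(self.loss_rate, dict)
            else [self.loss_rate]
        )
        if any(r < 0 for r in rates + [self.sub_rate, self.indel_rate]):
            raise ValueError("rates must be >= 0")

    def hazard(self, cls: str) -> float:
        if isinstance(self.loss_rate, dict):
            return self.loss_rate.get(cls, 0.0)
        return self.loss_rate


@dataclass
class SyntheticClade:
    """Reference genome, descendants, ground-truth chains and annotations."""

    reference: dict[str, str]
    descendants: dict[str, dict[str, str]]
    divergence_myr: dict[str, float]
    chains: dict[str, ChainMap]
    annotations: dict[str, list[tuple[str, int, int]]]
    params: EvolParams

    @property
    def species(self) -> list[str]:
        return sorted(self.descendants)


def random_genome(length: int, rng: np.random.Generator) -> str:
    if length <= 0:
        raise ValueError("genome length must be positive")
    return "".join(BASES[rng.integers(0, 4, size=length)])


def make_annotations(
    length: int, chrom: str = "chr1", period: int = 10_000
) -> dict[str, list[tuple[str, int, int]]]:
    """Deterministic annotation layout repeated every ``period`` bp.

    Each period carries a 1.2 kb accessible island, a 2 kb promoter
    immediately upstream of a 1.5 kb gene (so promoters are exactly the
    0-2 kb upstream of each gene start), the rest inaccessible intergenic.
    """
    ann: dict[str, list[tuple[str, int, int]]] = {
        "accessible": [],
        "promoter": [],
        "genic": [],
        "inaccessible": [],
    }
    for k in range(0, length, period):
        end = min(length, k + period)
        spans = [
            ("inaccessible", k, k + 1000),
            ("accessible", k + 1000, k + 2200),
            ("inaccessible", k + 2200, k + 2500),
            ("promoter", k + 2500, k + 4500),
            ("genic", k + 4500, k + 6000),
            ("inaccessible", k + 6000, k + period),
        ]
        for cls, s, e in spans:
            s, e = min(s, end), min(e, end)
            if e > s:
                ann[cls].append((chrom, s, e))
    return ann


def _class_runs(
    annotations: dict[str, list[tuple[str, int, int]]], chrom: str
) -> list[tuple[int, int, str]]:
    runs = [
        (s, e, cls)
        for cls, ivs in annotations.items()
        for c, s, e in ivs
        if c == chrom
    ]
    return sorted(runs)


def _evolve_branch(
    reference: str,
    chrom: str,
    t: float,
    params: EvolParams,
    annotations: dict[str, list[tuple[str, int, int]]],
    rng: np.random.Generator,
) -> tuple[str, list[Chain]]:
    """Evolve one branch; returns (descendant sequence, chains vs reference)."""
    L = len(reference)

    # --- segment loss: per annotation-class run, block-granular deletion
    survivors: list[tuple[int, int]] = []
    for s, e, cls in _class_runs(annotations, chrom):
        p_loss = 1.0 - math.exp(-params.hazard(cls) * t)
        pos = s
        while pos < e:
            block_end = min(e, pos + params.loss_block)
            if rng.random() >= p_loss:
                if survivors and survivors[-1][1] == pos:
                    survivors[-1] = (survivors[-1][0], block_end)
                else:
                    survivors.append((pos, block_end))
            pos = block_end

    # --- per-survivor indels and substitutions, building query + chains
    q_parts: list[str] = []
    q_pos = 0
    protochains = []  # (blocks_fwd, inverted, t_span, q_span)
    for s, e in survivors:
        seg = list(reference[s:e])
        seg_len = e - s
        # substitutions (multiple hits allowed)
        n_sub = rng.poisson(params.sub_rate * t * seg_len)
        for p in rng.integers(0, seg_len, size=n_sub):
            seg[p] = "ACGT".replace(seg[p], "")[rng.integers(0, 3)]
        # indels: positions within the segment, applied left to right
        n_indel = rng.poisson(params.indel_rate * t * seg_len)
        sites = np.sort(rng.integers(1, seg_len, size=n_indel)) if seg_len > 1 else []
        blocks = []  # (t_start, q_local, size) pre-inversion
        out_parts: list[str] = []
        t_cur, q_local = s, 0
        prev = 0
        for site in list(sites) + [seg_len]:
            site = int(site)
            if site < prev:  # swallowed by an earlier deletion
                continue
            if site > prev:
                piece = "".join(seg[prev:site])
                out_parts.append(piece)
                blocks.append((t_cur, q_local, site - prev))
                t_cur += site - prev
                q_local += site - prev
                prev = site
            if site == seg_len:
                break
            length = int(min(rng.geometric(params.indel_geom_p), params.indel_cap))
            if rng.random() < 0.5:  # insertion in the descendant
                ins = "".join(BASES[rng.integers(0, 4, size=length)])
                out_parts.append(ins)
                q_local += length
            else:  # deletion from the descendant
                skip = min(length, seg_len - site)
                t_cur += skip
                prev = site + skip
                if prev >= seg_len:
                    break
        if not blocks:
            continue
        q_seq = "".join(out_parts)
        inverted = rng.random() < (1.0 - math.exp(-params.inversion_rate * t))
        if inverted:
            q_seq = revcomp(q_seq)
            m = len(q_seq)
            blocks = [(t0, m - ql - size, size) for t0, ql, size in blocks]
        q_parts.append(q_seq)
        protochains.append((blocks, inverted, q_pos, len(q_seq)))
        q_pos += len(q_seq)

    q_genome = "".join(q_parts)
    q_size = len(q_genome)
    chains: list[Chain] = []
    for cid, (blocks, inverted, q_off, q_len) in enumerate(protochains, 1):
        if inverted:
            # forward offset of local x is q_off + x; raw minus-strand
            # coordinate of forward f is q_size - 1 - f
            raw_blocks = sorted(
                (t0, q_size - (q_off + ql + size), size) for t0, ql, size in blocks
            )
            strand = "-"
        else:
            raw_blocks = sorted((t0, q_off + ql, size) for t0, ql, size in blocks)
            strand = "+"
        aligned = sum(b[2] for b in raw_blocks)
        chains.append(
            Chain(
                score=float(aligned),
                t_name=chrom,
                t_size=L,
                t_start=raw_blocks[0][0],
                t_end=raw_blocks[-1][0] + raw_blocks[-1][2],
                q_name=chrom,
                q_size=q_size,
                q_strand=strand,
                q_start=raw_blocks[0][1],
                q_end=raw_blocks[-1][1] + raw_blocks[-1][2],
                chain_id=cid,
                blocks=tuple(raw_blocks),
            )
        )
    return q_genome, chains


def evolve_clade(
    reference_length: int,
    species_times: dict[str, float],
    params: EvolParams = EvolParams(),
    rng: np.random.Generator | None = None,
    chrom: str = "chr1",
    reference: str | None = None,
    annotations: dict[str, list[tuple[str, int, int]]] | None = None,
) -> SyntheticClade:
    """Generate a clade: reference plus descendants at the stated times.

    Branches are evolved independently from the reference (star phylogeny);
    the pairwise reference-descendant divergence time is what downstream
    rate fits consume.  A ready-made ``reference`` sequence and/or
    ``annotations`` may be supplied; otherwise they are generated.
    """
    if reference is None and reference_length < 10_000:
        raise ValueError("reference_length must be >= 10 kb")
    if any(t < 0 for t in species_times.values()):
        raise ValueError("divergence times must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    ref = reference if reference is not None else random_genome(reference_length, rng)
    ann = annotations if annotations is not None else make_annotations(len(ref), chrom)
    descendants, chains = {}, {}
    for sp in sorted(species_times):
        t = species_times[sp]
        if t == 0:
            descendants[sp] = ref
            chains[sp] = ChainMap(
                chains=[
                    Chain(
                        score=float(len(ref)),
                        t_name=chrom,
                        t_size=len(ref),
                        t_start=0,
                        t_end=len(ref),
                        q_name=chrom,
                        q_size=len(ref),
                        q_strand="+",
                        q_start=0,
                        q_end=len(ref),
                        chain_id=1,
                        blocks=((0, 0, len(ref)),),
                    )
                ]
            )
            continue
        q_genome, ch = _evolve_branch(ref, chrom, t, params, ann, rng)
        descendants[sp] = q_genome
        chains[sp] = ChainMap(chains=ch)
    return SyntheticClade(
        reference={chrom: ref},
        descendants={sp: {chrom: g} for sp, g in descendants.items()},
        divergence_myr=dict(species_times),
        chains=chains,
        annotations=ann,
        params=params,
    )


# ---------------------------------------------------------------------------
# ChIP read simulation


@dataclass
class BindingLandscape:
    """Binding sites per species plus the simulated mean fragment size L."""

    sites: dict[str, list[tuple[str, int, float]]]
    fragment_size: int = 200
    conservation_half_life: float = 30.0


def make_binding_landscape(
    clade: SyntheticClade,
    n_sites: int,
    rng: np.random.Generator,
    fragment_size: int = 200,
    conservation_half_life: float = 30.0,
    regions: list[tuple[str, int, int]] | None = None,
) -> BindingLandscape:
    """Place sites on the reference; conserve or turn them over per species.

    Sites are placed uniformly within ``regions`` (e.g. the clade's
    accessible chromatin; whole genome when None).  A reference site
    survives in a descendant with probability ``0.5 ** (t / half_life)``
    and must still map through the ground-truth chain; lost sites are
    replaced by novel sites -- drawn from the same regions, at loci that
    still exist in the descendant -- so the per-species site count stays
    constant (binding turnover within the permissive space, not binding
    loss).
    """
    (chrom, ref), = clade.reference.items()
    margin = 2 * fragment_size
    if regions is None:
        regions = [(chrom, margin, len(ref) - margin)]

    def draw_ref_position() -> int:
        lens = np.array([e - s for _c, s, e in regions], dtype=float)
        ridx = int(rng.choice(len(regions), p=lens / lens.sum()))
        _c, s, e = regions[ridx]
        return int(rng.integers(s, e))

    def map_through(chain_map: ChainMap, pos: int) -> int | None:
        for chain in chain_map.for_target(chrom):
            q = chain.q_forward(pos)
            if q is not None:
                return q
        return None

    positions = [draw_ref_position() for _ in range(n_sites)]
    strengths = rng.lognormal(mean=0.0, sigma=0.5, size=n_sites)
    ref_sites = [(chrom, int(p), float(s)) for p, s in zip(positions, strengths)]
    sites = {"reference": ref_sites}
    for sp in clade.species:
        t = clade.divergence_myr[sp]
        chain_map = clade.chains[sp]
        q_len = len(clade.descendants[sp][chrom])
        p_keep = 0.5 ** (t / conservation_half_life)
        sp_sites = []
        for c, pos, strength in ref_sites:
            mapped = map_through(chain_map, pos) if rng.random() < p_keep else None
            if mapped is not None and margin <= mapped < q_len - margin:
                sp_sites.append((c, int(mapped), strength))
                continue
            novel = None
            for _ in range(200):  # turnover: a new site in surviving region space
                cand = map_through(chain_map, draw_ref_position())
                if cand is not None and margin <= cand < q_len - margin:
                    novel = cand
                    break
            if novel is None:
                novel = int(rng.integers(margin, q_len - margin))
            sp_sites.append((c, novel, float(rng.lognormal(0.0, 0.5))))
        sites[sp] = sp_sites
    return BindingLandscape(
        sites=sites,
        fragment_size=fragment_size,
        conservation_half_life=conservation_half_life,
    )


def simulate_chip_reads(
    sites: list[tuple[str, int, float]],
    chrom_sizes: dict[str, int],
    n_reads: int,
    rng: np.random.Generator,
    fragment_size: int = 200,
    read_length: int = 36,
    background_fraction: float = 0.2,
    jitter_sd: float = 20.0,
) -> list[tuple[str, int, int, str, int, str]]:
    """Simulate tagAlign records around binding sites plus uniform background.

    Fragments of length ``fragment_size`` are centred on sites with Gaussian
    jitter; each sequenced read reports the fragment's 5' end on the plus
    strand or its 3' end on the minus strand.  Reads are allocated to sites
    proportionally to site strength.  Fragments poking past a chromosome
    end are truncated.  Records are (chrom, start, end, seq, score, strand).
    """
    records = []
    n_bg = int(round(n_reads * background_fraction))
    n_signal = n_reads - n_bg
    if sites and n_signal > 0:
        w = np.array([s for _c, _p, s in sites], dtype=float)
        w /= w.sum()
        counts = rng.multinomial(n_signal, w)
        for (chrom, pos, _s), k in zip(sites, counts):
            size = chrom_sizes[chrom]
            centers = pos + np.round(rng.normal(0, jitter_sd, size=k)).astype(int)
            strands = rng.random(k) < 0.5
            for c, plus in zip(centers, strands):
                fs = int(c) - fragment_size // 2
                fe = fs + fragment_size
                fs, fe = max(0, fs), min(size, fe)
                if fe - fs < read_length:
                    continue
                if plus:
                    start, end = fs, fs + read_length
                else:
                    start, end = fe - read_length, fe
                records.append((chrom, start, end, "N", 1000, "+" if plus else "-"))
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    for _ in range(n_bg):
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        chrom, size = chroms[ci], int(sizes[ci])
        fs = int(rng.integers(0, max(1, size - fragment_size)))
        fe = fs + fragment_size
        plus = rng.random() < 0.5
        if plus:
            start, end = fs, fs + read_length
        else:
            start, end = fe - read_length, fe
        records.append((chrom, start, end, "N", 1000, "+" if plus else "-"))
    return records


def write_tagalign(records, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, seq, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{seq}\t{score}\t{strand}\n")


def read_tagalign(path) -> list[tuple[str, int, int, str, int, str]]:
    records = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4]), f[5]))
    return records


# ---------------------------------------------------------------------------
# expression tables


def simulate_expression(
    n_genes: int,
    species_times: dict[str, float],
    decay_rate: float,
    rng: np.random.Generator,
    log2_mean: float = 3.0,
    log2_sd: float = 2.2,
) -> tuple[dict[str, pd.DataFrame], dict[str, dict[str, str]]]:
    """Orthologous TPM tables whose rank correlation decays as exp(rate * t).

    Reference log2 expression is Gaussian; each species' log2 expression is
    a correlated Gaussian whose latent Pearson correlation is chosen so the
    realised Spearman correlation approximates ``exp(decay_rate * t)`` (the
    Gaussian-copula relation rho = 2 sin(pi * r_s / 6)).  The log-normal
    TPM scale leaves a tail of genes under 5 TPM so abundance filters have
    something to remove.  Returns ``(tables, ortholog_maps)`` where tables
    include a ``"reference"`` entry and ortholog maps are one-to-one
    reference-to-species gene-id mappings.
    """
    if n_genes < 50:
        raise ValueError("n_genes must be >= 50")
    ref_ids = [f"g{i:05d}" for i in range(n_genes)]
    x0 = rng.normal(log2_mean, log2_sd, size=n_genes)
    tables = {
        "reference": pd.DataFrame(
            {"gene_id": ref_ids, "tpm": np.power(2.0, x0)}
        )
    }
    ortholog_maps: dict[str, dict[str, str]] = {}
    for sp in sorted(species_times):
        t = species_times[sp]
        r_s = math.exp(decay_rate * t)
        rho = min(1.0, 2.0 * math.sin(math.pi * r_s / 6.0))
        z = rng.normal(0.0, 1.0, size=n_genes)
        x = log2_mean + rho * (x0 - log2_mean) + math.sqrt(1 - rho**2) * log2_sd * z
        sp_ids = [f"{sp}_{g}" for g in ref_ids]
        tables[sp] = pd.DataFrame({"gene_id": sp_ids, "tpm": np.power(2.0, x)})
        ortholog_maps[sp] = dict(zip(ref_ids, sp_ids))
    return tables, ortholog_maps


# ---------------------------------------------------------------------------
# motif implantation


def implant_motifs(
    genome: dict[str, str],
    pwm,
    n_sites: int,
    rng: np.random.Generator,
    min_spacing: int = 10,
    min_score: float | None = None,
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Write PWM-sampled matches at non-overlapping random positions.

    Site sequences are drawn column-wise from the motif's probability
    matrix, conditioned on scoring at least ``min_score`` (by default the
    motif's own significance cutoff at the conventional 1e-4 level) so the
    implanted sequences really are matches.  Returns the modified genome
    and the truth BED of implanted locations.  Raises if the genome cannot
    host the requested sites.
    """
    from .motifs import ALPHABET, pwm_pvalue_threshold

    if min_score is None:
        min_score = pwm_pvalue_threshold(pwm, 1e-4)
    width = pwm.length
    (chrom, seq), = genome.items()
    if width >= len(seq):
        raise ValueError("PWM longer than chromosome")
    if n_sites == 0:
        return dict(genome), []
    if n_sites * (width + min_spacing) > len(seq) // 2:
        raise ValueError("insufficient space for requested sites")
    seq_list = list(seq)
    placed: list[int] = []
    truth = []
    attempts = 0
    while len(truth) < n_sites:
        attempts += 1
        if attempts > 200 * n_sites:
            raise ValueError("could not place sites without overlap")
        s = int(rng.integers(0, len(seq) - width))
        if any(abs(s - p) < width + min_spacing for p in placed):
            continue
        for _draw in range(1000):
            codes = [
                int(rng.choice(4, p=pwm.probabilities[j])) for j in range(width)
            ]
            score = sum(pwm.log_odds[j, c] for j, c in enumerate(codes))
            if score >= min_score - 5e-4:  # half a score-lattice step
                break
        else:
            raise ValueError("PWM cannot produce sites at its own cutoff")
        site = "".join(ALPHABET[c] for c in codes)
        seq_list[s : s + width] = site
        placed.append(s)
        truth.append((chrom, s, s + width))
    return {chrom: "".join(seq_list)}, sorted(truth)
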