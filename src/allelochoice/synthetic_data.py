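"""Synthetic hybrid-clone data generator.

Emulates the statistical structure of allele-resolved assays on F1 hybrid
(B6 x Cast) pre-B-cell clones: a V-segment locus with a fixed subset of
segments that have the potential to be activated, independent per-allele
Bernoulli activation in each clone, overdispersed (negative-binomial) read
counts with leakage from inactive alleles, optional fixed per-segment genetic
bias toward one allele, pools of many independent clones, SNP-bearing read
pairs for haplotype tagging, and rearrangement repertoires whose V usage is
coupled to the non-coding-RNA signal of the activated segments.

All randomness flows from an explicit seed; child generators are derived
deterministically with :class:`numpy.random.SeedSequence` so that every
generator is bit-reproducible and a one-clone pool equals a single simulated
clone under the same seed discipline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activation_model import ActivationModelParams

#: minimum gap between consecutive segment spans; large enough that the
#: strand-aware assignment windows (10,000 bp one way, 500 bp the other) of
#: neighbouring segments are disjoint for any strand combination.
MIN_GAP = 21_000
MAX_GAP = 30_000
SEG_LEN_RANGE = (300, 500)
DEFAULT_CHROM = "chr6"


@dataclass(frozen=True)
class VSegment:
    """An annotated V segment: the unit of allelic choice."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    functional: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"segment {self.id}: need 0 <= start < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"segment {self.id}: strand must be + or -")


@dataclass(frozen=True)
class Locus:
    """A V-segment locus annotation plus the fixed set of activatable segments."""

    segments: tuple[VSegment, ...]
    potential_set: frozenset[str]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("segment ids must be unique within a locus")
        unknown = self.potential_set - set(ids)
        if unknown:
            raise ValueError(f"potential_set contains unknown segments: {sorted(unknown)}")

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def segment_ids(self) -> list[str]:
        return [s.id for s in self.segments]


@dataclass(frozen=True)
class CloneState:
    """Per-segment allelic activation state of one clone (fixed for its lifetime)."""

    clone_id: str
    activation: dict  # segment id -> (b6_active, cast_active)
    potential_set: frozenset[str]

    def category(self, seg_id: str) -> str:
        b6, cast = self.activation[seg_id]
        if b6 and cast:
            return "biallelic"
        if b6:
            return "mono_b6"
        if cast:
            return "mono_cast"
        return "silent"


@dataclass(frozen=True)
class CountNoiseParams:
    """Negative-binomial (Gamma-Poisson) count noise for allele-resolved reads.

    ``mu_active`` / ``mu_leak`` are the mean allele-informative read counts for
    an active / inactive allele of a segment; ``dispersion`` is the NB
    overdispersion alpha (variance = mu + alpha*mu^2).  Leakage defaults to 1%
    of the active mean: inactive alleles are depleted, not signal-free.
    """

    mu_active: float = 100.0
    mu_leak: float = 1.0
    dispersion: float = 0.1
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if not (self.mu_active > self.mu_leak >= 0):
            raise ValueError("need mu_active > mu_leak >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class SnpRecord:
    """A discriminating single-nucleotide polymorphism between the parental genomes."""

    chrom: str
    pos: int  # 0-based
    b6_base: str
    cast_base: str

    def __post_init__(self) -> None:
        if self.b6_base == self.cast_base:
            raise ValueError("SNP must differ between the parental alleles")


@dataclass(frozen=True)
class ReadPairInterval:
    """The genomic span of a read pair with its SNP observations (pos, base)."""

    chrom: str
    start: int
    end: int
    strand: str
    snp_observations: tuple = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("read span must be non-empty")
        for pos, _ in self.snp_observations:
            if not (self.start <= pos < self.end):
                raise ValueError("SNP observation outside read span")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_locus(n_total: int, n_potential: int, seed, chrom: str = DEFAULT_CHROM) -> Locus:
    """Lay out ``n_total`` functional V segments and fix a potential set of size ``n_potential``.

    Segments are placed left to right with random lengths and inter-segment gaps
    exceeding :data:`MIN_GAP`, so the strand-aware assignment windows used by
    read assignment are pairwise disjoint regardless of strand.  Strands are
    random.  The potential set is a uniformly drawn fixed subset: every clone
    simulated from this locus shares it.
    """
    if n_total < 0 or n_potential < 0:
        raise ValueError("segment counts must be nonnegative")
    if n_potential > n_total:
        raise ValueError("n_potential cannot exceed n_total")
    rng = _rng(seed)
    segments = []
    pos = int(rng.integers(20_000, 40_000))
    for i in range(n_total):
        length = int(rng.integers(*SEG_LEN_RANGE))
        strand = "+" if rng.random() < 0.5 else "-"
        segments.append(
            VSegment(id=f"V{i + 1:03d}", chrom=chrom, start=pos, end=pos + length, strand=strand)
        )
        pos += length + int(rng.integers(MIN_GAP + 1, MAX_GAP))
    potential = rng.choice(n_total, size=n_potential, replace=False) if n_potential else []
    potential_ids = frozenset(segments[i].id for i in np.sort(np.asarray(potential, dtype=int)))
    return Locus(segments=tuple(segments), potential_set=potential_ids)


def simulate_clone(
    locus: Locus, params: ActivationModelParams, seed, clone_id: str = "clone"
) -> CloneState:
    """Draw one clone's activation state: independent Bernoulli trials per allele.

    Each segment in the locus potential set activates on the B6 allele with
    probability ``params.p_b6`` and, independently, on the Cast allele with
    probability ``params.p_cast``; all other segments stay silent.
    """
    rng = _rng(seed)
    activation = {}
    for seg in locus:
        if seg.id in locus.potential_set:
            activation[seg.id] = (
                bool(rng.random() < params.p_b6),
                bool(rng.random() < params.p_cast),
            )
        else:
            activation[seg.id] = (False, False)
    return CloneState(clone_id=clone_id, activation=activation, potential_set=locus.potential_set)


def _nb_draw(rng: np.random.Generator, mu: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial counts with mean mu and variance mu + dispersion*mu^2."""
    if mu <= 0:
        return np.zeros(size, dtype=int)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size).astype(int)


def simulate_counts(
    clone: CloneState,
    noise: CountNoiseParams,
    bias: dict | None = None,
    seed=0,
    sample_prefix: str | None = None,
) -> pd.DataFrame:
    """Allele-resolved count table for one clone: replicates of NB counts per segment.

    For each segment and replicate the B6 (Cast) count is negative-binomial
    with mean ``mu_active`` if that allele is active, else ``mu_leak``.  An
    optional ``bias`` maps segment ids to a multiplicative factor applied to
    the Cast mean — a fixed genetic preference of that segment for one allele
    (>1 favours Cast, <1 favours B6).  Replicates are independent resamples of
    the same clone state.

    Returns a long-format table with columns ``feature_id, sample, b6, cast``.
    """
    bias = dict(bias or {})
    unknown = set(bias) - set(clone.activation)
    if unknown:
        raise ValueError(f"bias refers to unknown segments: {sorted(unknown)}")
    rng = _rng(seed)
    prefix = sample_prefix if sample_prefix is not None else clone.clone_id
    rows = []
    for seg_id in clone.activation:
        b6_on, cast_on = clone.activation[seg_id]
        mu_b6 = noise.mu_active if b6_on else noise.mu_leak
        mu_cast = (noise.mu_active if cast_on else noise.mu_leak) * bias.get(seg_id, 1.0)
        b6 = _nb_draw(rng, mu_b6, noise.dispersion, noise.n_replicates)
        cast = _nb_draw(rng, mu_cast, noise.dispersion, noise.n_replicates)
        for rep in range(noise.n_replicates):
            rows.append((seg_id, f"{prefix}_rep{rep + 1}", int(b6[rep]), int(cast[rep])))
    return pd.DataFrame(rows, columns=["feature_id", "sample", "b6", "cast"])


def simulate_pool(
    locus: Locus,
    params: ActivationModelParams,
    n_clones: int,
    noise: CountNoiseParams,
    bias: dict | None = None,
    seed=0,
    sample_prefix: str = "pool",
) -> pd.DataFrame:
    """Counts for a pool of ``n_clones`` independent clones (summed per segment/replicate).

    Emulates an ex-vivo bone-marrow pool: a mixture of clones whose
    individually monoallelic choices average out, so pooled segments look
    biallelic unless a fixed genetic bias skews them.
    """
    if n_clones < 1:
        raise ValueError("a pool needs at least one clone")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_clones)
    total: pd.DataFrame | None = None
    for i in range(n_clones):
        clone = simulate_clone(locus, params, children[2 * i], clone_id=f"pool_clone{i}")
        tbl = simulate_counts(clone, noise, bias=bias, seed=children[2 * i + 1],
                              sample_prefix=sample_prefix)
        if total is None:
            total = tbl
        else:
            # every per-clone table shares the same (feature_id, sample) rows
            total[["b6", "cast"]] = total[["b6", "cast"]].to_numpy() + tbl[["b6", "cast"]].to_numpy()
    return total


def make_snps(locus: Locus, per_segment: int = 20, seed=0) -> list[SnpRecord]:
    """Scatter discriminating SNPs across each segment's assignment window.

    The two parental genomes diverge at roughly 1% of positions genome wide,
    so informative SNPs occur throughout the transcribed window, not only in
    the segment body; ``per_segment`` positions per window (default 20, about
    one per 550 bp) keeps most read pairs taggable.
    """
    from .allelic_assignment import assignment_window

    rng = _rng(seed)
    bases = np.array(list("ACGT"))
    snps: list[SnpRecord] = []
    for seg in locus:
        lo, hi = assignment_window(seg)
        positions = np.sort(
            rng.choice(np.arange(lo, hi), size=min(per_segment, hi - lo), replace=False)
        )
        for pos in positions:
            b6, cast = rng.choice(bases, size=2, replace=False)
            snps.append(SnpRecord(chrom=seg.chrom, pos=int(pos), b6_base=str(b6), cast_base=str(cast)))
    return snps


def simulate_reads(
    clone: CloneState,
    locus: Locus,
    snps: list[SnpRecord],
    noise: CountNoiseParams,
    bias: dict | None = None,
    seed=0,
    read_span: int = 300,
) -> list[ReadPairInterval]:
    """Emit allele-bearing read-pair intervals for one clone (one library).

    Per (segment, allele) the number of read pairs follows the same
    negative-binomial noise model as :func:`simulate_counts` (one replicate).
    Each read pair is placed uniformly inside the segment's assignment window
    on the segment's strand and carries the parental base at every SNP it
    covers.  A window without SNPs triggers a warning: its reads are emitted
    but cannot be haplotype-tagged.
    """
    from .allelic_assignment import assignment_window

    bias = dict(bias or {})
    rng = _rng(seed)
    snp_by_chrom: dict[str, list[SnpRecord]] = {}
    for s in snps:
        snp_by_chrom.setdefault(s.chrom, []).append(s)
    reads: list[ReadPairInterval] = []
    seg_by_id = {s.id: s for s in locus}
    for seg_id, (b6_on, cast_on) in clone.activation.items():
        seg = seg_by_id[seg_id]
        win_start, win_end = assignment_window(seg)
        span = min(read_span, win_end - win_start)
        window_snps = [
            s for s in snp_by_chrom.get(seg.chrom, []) if win_start <= s.pos < win_end
        ]
        if not window_snps:
            warnings.warn(
                f"assignment window of {seg.id} contains no SNP; its reads are untaggable",
                stacklevel=2,
            )
        for allele, active in (("b6", b6_on), ("cast", cast_on)):
            mu = noise.mu_active if active else noise.mu_leak
            if allele == "cast":
                mu *= bias.get(seg_id, 1.0)
            n_reads = int(_nb_draw(rng, mu, noise.dispersion, 1)[0])
            if n_reads == 0:
                continue
            starts = rng.integers(win_start, win_end - span + 1, size=n_reads)
            for st in starts:
                st = int(st)
                obs = tuple(
                    (s.pos, s.b6_base if allele == "b6" else s.cast_base)
                    for s in window_snps
                    if st <= s.pos < st + span
                )
                reads.append(
                    ReadPairInterval(
                        chrom=seg.chrom, start=st, end=st + span, strand=seg.strand,
                        snp_observations=obs,
                    )
                )
    return reads


def simulate_repertoire(
    clone: CloneState,
    ncrna_table: pd.DataFrame,
    coupling: float = 0.9,
    early_allele: str = "B6",
    time_fraction: float = 1.0,
    n_events: int = 100_000,
    seed=0,
) -> pd.DataFrame:
    """Rearrangement repertoire coupled to the clone's ncRNA signal.

    Per allele, V segments are drawn multinomially with weights
    ``coupling * (segment's share of that allele's ncRNA counts) +
    (1 - coupling) * uniform over the allele's active segments``.  The total
    event count is split between the alleles so the early-replicating allele
    receives fraction ``1 - time_fraction/2`` of events: at ``time_fraction=0``
    all rearrangement is on the early allele, at 1 the alleles contribute
    equally.  An allele with no active segment yields an empty, flagged
    repertoire.

    Returns a table with columns ``v_id, allele, count, percent`` where percent
    is normalised within allele.
    """
    if not (0.0 <= coupling <= 1.0 and 0.0 <= time_fraction <= 1.0):
        raise ValueError("coupling and time_fraction must lie in [0, 1]")
    if early_allele not in {"B6", "Cast"}:
        raise ValueError("early_allele must be 'B6' or 'Cast'")
    rng = _rng(seed)
    pooled = ncrna_table.groupby("feature_id")[["b6", "cast"]].sum()
    seg_ids = list(pooled.index)
    early_frac = 1.0 - time_fraction / 2.0
    n_early = int(rng.binomial(n_events, early_frac))
    totals = {"B6": n_early, "Cast": n_events - n_early}
    if early_allele == "Cast":
        totals = {"B6": totals["Cast"], "Cast": totals["B6"]}
    rows = []
    for allele, col, idx in (("B6", "b6", 0), ("Cast", "cast", 1)):
        active = np.array([clone.activation.get(sid, (False, False))[idx] for sid in seg_ids])
        if not active.any():
            warnings.warn(f"clone {clone.clone_id}: no active segment on the {allele} allele; "
                          "empty repertoire", stacklevel=2)
            continue
        # only activated (open) segments can rearrange: leak signal from closed
        # segments carries no weight
        ncrna = pooled[col].to_numpy(dtype=float) * active
        share = ncrna / ncrna.sum() if ncrna.sum() > 0 else active / active.sum()
        uniform = active / active.sum()
        weights = coupling * share + (1.0 - coupling) * uniform
        weights = weights / weights.sum()
        counts = rng.multinomial(totals[allele], weights)
        pct = 100.0 * counts / counts.sum() if counts.sum() else np.zeros_like(counts, dtype=float)
        for sid, c, p in zip(seg_ids, counts, pct):
            rows.append((sid, allele, int(c), float(p)))
    return pd.DataFrame(rows, columns=["v_id", "allele", "count", "percent"])
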