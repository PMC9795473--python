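"""Synthetic mock-community generator with a planted-error ledger.

Generates reference replicons (i.i.d. bases at a drawn GC), an "assembly"
that tiles each replicon into contigs while planting gaps, substitutions,
uncalled bases, and misassemblies of every category the classifier knows,
and paired-end reads under an even or logarithmic abundance profile.
Every planted edit is recorded in a :class:`TruthSet`, which acts as the
ground-truth oracle for the evaluation metrics.

The error model is deliberately plain — i.i.d. substitutions and uncalled
bases, no indel or position-dependent error profile — which is enough to
exercise every metric while keeping expectations analytic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import SequenceRecord, reverse_complement

__all__ = ["SimulationConfig", "TruthSet", "PlantedMisassembly",
           "SourceInterval", "simulate_replicons", "simulate_assembly",
           "simulate_reads", "simulate_community"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one synthetic community.

    Lengths in bases, rates as per-base probabilities.  ``seed`` is
    mandatory: all randomness flows from it through named substreams, so a
    config reproduces byte-identical communities.
    """

    n_replicons: int = 5
    length_range: tuple[int, int] = (100_000, 500_000)
    gc_range: tuple[float, float] = (0.35, 0.65)
    abundance_mode: str = "even"
    substitution_rate: float = 0.0
    n_rate: float = 0.0
    contig_len_distribution: tuple[float, float] = (20_000.0, 5_000.0)
    # tiling never emits contigs below this, so the default 1 kb filtered
    # set keeps every tile and planted gaps stay the only uncovered bases
    min_contig_len: int = 1000
    planted_gaps: tuple[tuple[int, int], ...] = ()
    planted_misassemblies: tuple[tuple[str, int], ...] = ()
    read_len: int = 150
    n_read_pairs: int = 2000
    insert_size: int = 350
    read_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.n_rate, self.read_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.abundance_mode not in ("even", "log"):
            raise ValueError("abundance_mode must be 'even' or 'log'")


@dataclass(frozen=True)
class SourceInterval:
    """Where a slice of a contig came from on the reference."""

    contig_id: str
    contig_start: int
    contig_end: int
    replicon_id: str
    t_start: int
    t_end: int
    strand: str


@dataclass(frozen=True)
class PlantedMisassembly:
    category: str
    contig_id: str
    magnitude: int


@dataclass
class TruthSet:
    """Ledger of every planted edit; the oracle for acceptance tests."""

    source_intervals: list[SourceInterval] = field(default_factory=list)
    substitutions: list[tuple[str, int]] = field(default_factory=list)
    uncalled: list[tuple[str, int]] = field(default_factory=list)
    gap_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    misassemblies: list[PlantedMisassembly] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "source_intervals": [asdict(s) for s in self.source_intervals],
            "substitutions": self.substitutions,
            "uncalled": self.uncalled,
            "gap_intervals": self.gap_intervals,
            "misassemblies": [asdict(m) for m in self.misassemblies],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _random_sequence(rng: np.random.Generator, length: int,
                     gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def simulate_replicons(cfg: SimulationConfig) -> list[SequenceRecord]:
    """Draw the community's replicons; deterministic under the seed."""
    rng = _rng(cfg, 0)
    out = []
    for i in range(cfg.n_replicons):
        length = int(rng.integers(cfg.length_range[0],
                                  cfg.length_range[1] + 1))
        gc = float(rng.uniform(*cfg.gc_range))
        out.append(SequenceRecord(f"replicon_{i:02d}",
                                  _random_sequence(rng, length, gc)))
    return out


def _overlaps_any(start: int, end: int,
                  forbidden: Sequence[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in forbidden)


def _draw_clear_interval(rng: np.random.Generator, replicon_len: int,
                         span: int, forbidden: Sequence[tuple[int, int]],
                         tries: int = 200) -> tuple[int, int]:
    """An interval of ``span`` bases avoiding the forbidden intervals."""
    if span > replicon_len:
        raise ValueError("requested interval exceeds replicon length")
    for _ in range(tries):
        s = int(rng.integers(0, replicon_len - span + 1))
        if not _overlaps_any(s, s + span, forbidden):
            return s, s + span
    raise RuntimeError("could not place an interval clear of planted gaps")


def _apply_point_errors(seq: str, rng: np.random.Generator,
                        cfg: SimulationConfig, contig_id: str,
                        truth: TruthSet) -> str:
    """Plant i.i.d. substitutions and uncalled bases; ledger each one."""
    if cfg.substitution_rate == 0.0 and cfg.n_rate == 0.0:
        return seq
    arr = np.array(list(seq))
    n = len(arr)
    sub_hits: set[int] = set()
    if cfg.substitution_rate > 0.0:
        for pos in np.nonzero(rng.random(n) < cfg.substitution_rate)[0]:
            old = arr[pos]
            choices = [b for b in "ACGT" if b != old]
            arr[pos] = choices[int(rng.integers(3))]
            sub_hits.add(int(pos))
            truth.substitutions.append((contig_id, int(pos)))
    if cfg.n_rate > 0.0:
        for pos in np.nonzero(rng.random(n) < cfg.n_rate)[0]:
            if int(pos) not in sub_hits:
                arr[pos] = "N"
                truth.uncalled.append((contig_id, int(pos)))
    return "".join(arr)


def _tile_replicon(rep: SequenceRecord, rep_gaps: list[tuple[int, int]],
                   rng: np.random.Generator, cfg: SimulationConfig,
                   truth: TruthSet, counter: list[int]
                   ) -> list[SequenceRecord]:
    """Cut the replicon (minus planted gaps) into contiguous contigs."""
    mean, sd = cfg.contig_len_distribution
    boundaries = sorted(rep_gaps)
    segments: list[tuple[int, int]] = []
    cursor = 0
    for s, e in boundaries:
        if s > cursor:
            segments.append((cursor, s))
        cursor = e
    if cursor < rep.length:
        segments.append((cursor, rep.length))

    contigs: list[SequenceRecord] = []
    for seg_s, seg_e in segments:
        pos = seg_s
        while pos < seg_e:
            want = int(max(cfg.min_contig_len, rng.normal(mean, sd)))
            end = min(pos + want, seg_e)
            if seg_e - end < cfg.min_contig_len:
                end = seg_e  # absorb the remainder rather than emit a stub
            cid = f"contig_{counter[0]:05d}"
            counter[0] += 1
            seq = _apply_point_errors(rep.seq[pos:end], rng, cfg, cid, truth)
            truth.source_intervals.append(SourceInterval(
                cid, 0, end - pos, rep.id, pos, end, "+"))
            contigs.append(SequenceRecord(cid, seq))
            pos = end
    return contigs


def _plant_misassembly(category: str, magnitude: int,
                       replicons: Sequence[SequenceRecord],
                       gaps_by_rep: dict[str, list[tuple[int, int]]],
                       rng: np.random.Generator, cfg: SimulationConfig,
                       truth: TruthSet, counter: list[int]
                       ) -> SequenceRecord:
    """Build one misassembled contig from its generative template."""
    cid = f"contig_{counter[0]:05d}"
    counter[0] += 1

    def seg_for(rep: SequenceRecord) -> int:
        # flank long enough to anchor cleanly, short enough to place even
        # on small replicons alongside planted gaps
        return int(max(500, min(cfg.contig_len_distribution[0] // 4,
                                rep.length // 8)))

    def clear(rep: SequenceRecord, span: int) -> tuple[int, int]:
        return _draw_clear_interval(rng, rep.length, span,
                                    gaps_by_rep.get(rep.id, []))

    if category == "chimera":
        if len(replicons) < 2:
            raise ValueError("a chimera needs at least 2 replicons")
        ra, rb = rng.choice(len(replicons), size=2, replace=False)
        a, b = replicons[int(ra)], replicons[int(rb)]
        seg = min(seg_for(a), seg_for(b))
        (as_, ae), (bs, be) = clear(a, seg), clear(b, seg)
        seq = a.seq[as_:ae] + b.seq[bs:be]
        truth.source_intervals += [
            SourceInterval(cid, 0, seg, a.id, as_, ae, "+"),
            SourceInterval(cid, seg, 2 * seg, b.id, bs, be, "+")]
    else:
        rep = replicons[int(rng.integers(len(replicons)))]
        seg = seg_for(rep)
        forbidden = gaps_by_rep.get(rep.id, [])
        if category == "insertion":
            s, e = _draw_clear_interval(rng, rep.length, 2 * seg, forbidden)
            mid = s + seg
            filler = _random_sequence(rng, magnitude, 0.5)
            seq = rep.seq[s:mid] + filler + rep.seq[mid:e]
            truth.source_intervals += [
                SourceInterval(cid, 0, seg, rep.id, s, mid, "+"),
                SourceInterval(cid, seg + magnitude, 2 * seg + magnitude,
                               rep.id, mid, e, "+")]
        elif category in ("deletion", "translocation"):
            span = 2 * seg + magnitude
            s, e = _draw_clear_interval(rng, rep.length, span, forbidden)
            mid = s + seg
            seq = rep.seq[s:mid] + rep.seq[mid + magnitude:e]
            truth.source_intervals += [
                SourceInterval(cid, 0, seg, rep.id, s, mid, "+"),
                SourceInterval(cid, seg, 2 * seg, rep.id,
                               mid + magnitude, e, "+")]
        elif category == "inversion":
            span = 2 * seg + magnitude
            s, e = _draw_clear_interval(rng, rep.length, span, forbidden)
            m1, m2 = s + seg, s + seg + magnitude
            seq = (rep.seq[s:m1] + reverse_complement(rep.seq[m1:m2])
                   + rep.seq[m2:e])
            truth.source_intervals += [
                SourceInterval(cid, 0, seg, rep.id, s, m1, "+"),
                SourceInterval(cid, seg, seg + magnitude, rep.id, m1, m2, "-"),
                SourceInterval(cid, seg + magnitude, span, rep.id, m2, e, "+")]
        elif category == "duplication":
            s, e = _draw_clear_interval(rng, rep.length, 2 * seg, forbidden)
            mid = s + seg
            seq = rep.seq[s:mid] + rep.seq[mid - magnitude:e]
            truth.source_intervals += [
                SourceInterval(cid, 0, seg, rep.id, s, mid, "+"),
                SourceInterval(cid, seg, seg + (e - mid) + magnitude, rep.id,
                               mid - magnitude, e, "+")]
        elif category == "rearrangement":
            span = 2 * seg
            s, e = _draw_clear_interval(rng, rep.length, span, forbidden)
            mid = s + seg
            seq = rep.seq[mid:e] + rep.seq[s:mid]
            truth.source_intervals += [
                SourceInterval(cid, 0, seg, rep.id, mid, e, "+"),
                SourceInterval(cid, seg, 2 * seg, rep.id, s, mid, "+")]
        else:
            raise ValueError(f"unknown misassembly category {category!r}")
    truth.misassemblies.append(PlantedMisassembly(category, cid, magnitude))
    return SequenceRecord(cid, seq)


def simulate_assembly(replicons: Sequence[SequenceRecord],
                      cfg: SimulationConfig
                      ) -> tuple[list[SequenceRecord], TruthSet]:
    """Tile the replicons into contigs with every configured planted error.

    Planted gaps are left uncovered by the tiling; planted misassemblies
    are emitted as extra dedicated contigs whose source segments avoid the
    planted gap regions (so the gap ledger stays exact).
    """
    if not replicons:
        raise ValueError("cannot simulate an assembly of zero replicons")
    rng = _rng(cfg, 1)
    truth = TruthSet()

    gaps_by_rep: dict[str, list[tuple[int, int]]] = {}
    for rep_idx, gap_len in cfg.planted_gaps:
        rep = replicons[rep_idx]
        if gap_len >= rep.length:
            raise ValueError(f"planted gap of {gap_len} bases exceeds "
                             f"replicon {rep.id} ({rep.length} bases)")
        s, e = _draw_clear_interval(rng, rep.length, gap_len,
                                    gaps_by_rep.get(rep.id, []))
        gaps_by_rep.setdefault(rep.id, []).append((s, e))
        truth.gap_intervals.append((rep.id, s, e))

    counter = [0]
    contigs: list[SequenceRecord] = []
    for rep in replicons:
        contigs += _tile_replicon(rep, gaps_by_rep.get(rep.id, []), rng,
                                  cfg, truth, counter)
    for category, magnitude in cfg.planted_misassemblies:
        contigs.append(_plant_misassembly(category, magnitude, replicons,
                                          gaps_by_rep, rng, cfg, truth,
                                          counter))
    return contigs, truth


def _abundance_weights(cfg: SimulationConfig, n: int) -> np.ndarray:
    if cfg.abundance_mode == "even":
        w = np.ones(n)
    else:  # logarithmic: each next replicon 10x less abundant
        w = 10.0 ** (-np.arange(n, dtype=float))
    return w / w.sum()


def simulate_reads(replicons: Sequence[SequenceRecord],
                   cfg: SimulationConfig
                   ) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Paired-end reads under the configured abundance profile.

    Fragments are sampled uniformly within the chosen replicon; R2 is the
    reverse complement of the fragment end.  Per-base substitution errors
    at ``read_error_rate``.
    """
    if not replicons:
        raise ValueError("cannot simulate reads from zero replicons")
    shortest = min(r.length for r in replicons)
    if cfg.read_len > shortest:
        raise ValueError("read length exceeds the shortest replicon")
    rng = _rng(cfg, 2)
    weights = _abundance_weights(cfg, len(replicons))
    insert = max(cfg.insert_size, cfg.read_len)
    r1s: list[SequenceRecord] = []
    r2s: list[SequenceRecord] = []
    choices = rng.choice(len(replicons), size=cfg.n_read_pairs, p=weights)
    for i, ri in enumerate(choices):
        rep = replicons[int(ri)]
        frag = min(insert, rep.length)
        start = int(rng.integers(0, rep.length - frag + 1))
        fragment = rep.seq[start:start + frag]
        fwd = fragment[:cfg.read_len]
        rev = reverse_complement(fragment)[:cfg.read_len]
        if cfg.read_error_rate > 0.0:
            fwd = _mutate(fwd, rng, cfg.read_error_rate)
            rev = _mutate(rev, rng, cfg.read_error_rate)
        r1s.append(SequenceRecord(f"read_{i:06d}/1", fwd))
        r2s.append(SequenceRecord(f"read_{i:06d}/2", rev))
    return r1s, r2s


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for pos in hits:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_community(cfg: SimulationConfig
                       ) -> tuple[list[SequenceRecord],
                                  list[SequenceRecord], TruthSet]:
    """Convenience: replicons plus one assembly with its truth ledger."""
    replicons = simulate_replicons(cfg)
    contigs, truth = simulate_assembly(replicons, cfg)
    return replicons, contigs, truth
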