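"""GU cleavage-site scanning, accessibility ranking, and off-target search.

Pistol ribozymes cleave 3' of the G of a GU dinucleotide, so every GU on
the target is a candidate site.  Candidates are ranked by how unpaired the
site and the two binding-arm footprints are in the local thermodynamic
ensemble (see :mod:`pistolkit.fold`); the design workflow is: scan,
fold a local window around each site, score, rank, then screen the chosen
arms against a transcriptome for off-target complementarity with a
seed-and-extend search.

Position convention: ``CleavageSite.position`` is the 1-based index of the
G, in the declared frame (``transcript`` or ``cds``).  The
:func:`calibrate_convention` helper resolves which convention a published
position list uses by finding the unique convention under which every
listed position lands on a GU.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, MissingFeatureError
from .fold import EnergyModel, FoldResult, partition_fold
from .seq_io import Region, Transcript, reverse_complement

__all__ = [
    "CleavageSite",
    "AccessibilityProfile",
    "OffTargetHit",
    "ScanConfig",
    "ScoreWeights",
    "OffTargetConfig",
    "find_gu_sites",
    "fold_window",
    "score_site",
    "rank_sites",
    "scan_target",
    "off_target_scan",
    "calibrate_convention",
]


@dataclass(frozen=True)
class CleavageSite:
    """A candidate GU cleavage site (position = 1-based index of the G)."""

    transcript_id: str
    position: int
    frame: str = "transcript"
    context5: str = ""
    context3: str = ""
    accessibility: float | None = None
    rank_score: float | None = None


@dataclass
class AccessibilityProfile:
    """Ensemble accessibility of one folded window.

    Wraps a :class:`~pistolkit.fold.FoldResult` together with the window it
    covers, so site positions (frame coordinates) can be mapped onto the
    pair-probability matrix.
    """

    window: Region
    fold: FoldResult

    @property
    def pair_probability(self) -> np.ndarray:
        return self.fold.pair_probability

    @property
    def unpaired_probability(self) -> np.ndarray:
        return self.fold.unpaired_probability

    @property
    def partition_function(self) -> float:
        return self.fold.partition_function

    @property
    def log_partition(self) -> float:
        return self.fold.log_partition

    def q_at(self, position: int) -> float:
        """Unpaired probability at a 1-based frame position inside the window."""
        idx = position - self.window.start
        if not 0 <= idx < len(self.fold.sequence):
            raise ConfigError(f"position {position} outside window {self.window}")
        return float(self.unpaired_probability[idx])


@dataclass(frozen=True)
class OffTargetHit:
    """A transcriptome segment complementary to the ribozyme's arm footprint."""

    transcript_id: str
    position: int  # 1-based start of the matched segment
    matched_length: int
    mismatches: int
    gu_at_junction: bool


@dataclass(frozen=True)
class ScoreWeights:
    """Relative weights for the GU dinucleotide and the two arm footprints."""

    gu: float = 1.0
    p1: float = 1.0
    p3: float = 1.0

    def __post_init__(self) -> None:
        if self.gu < 0 or self.p1 < 0 or self.p3 < 0 or (self.gu + self.p1 + self.p3) == 0:
            raise ConfigError("score weights must be non-negative and not all zero")


@dataclass(frozen=True)
class ScanConfig:
    """Pipeline parameters: folding window, arm footprints, scoring weights."""

    window_size: int = 120
    context: int = 10
    p1_len: int = 8
    p3_len: int = 16
    weights: ScoreWeights = ScoreWeights()
    energy_model: EnergyModel = EnergyModel()


@dataclass(frozen=True)
class OffTargetConfig:
    """Seed-and-extend parameters for the complementarity search.

    The exact-match seed is centred on the GU junction of the footprint;
    up to ``max_mismatches`` mismatches are tolerated outside the seed.
    """

    seed_length: int = 12
    max_mismatches: int = 2


def _frame_sequence(target: Transcript, frame: str) -> str:
    if frame == "cds":
        if target.cds is None:
            raise MissingFeatureError(
                f"cds frame requested but transcript {target.id!r} has no CDS annotation"
            )
        return target.cds_sequence()
    return target.sequence


def find_gu_sites(target: Transcript, frame: str = "transcript",
                  context: int = 10) -> list[CleavageSite]:
    """All GU dinucleotide positions on the target, ascending, with flanks.

    Overlapping occurrences are all reported; masked (N) positions never
    form a site.  Contexts are clipped at the sequence ends.
    """
    seq = _frame_sequence(target, frame)
    sites = []
    for i in range(len(seq) - 1):
        if seq[i] == "G" and seq[i + 1] == "U":
            sites.append(
                CleavageSite(
                    transcript_id=target.id,
                    position=i + 1,
                    frame=frame,
                    context5=seq[max(0, i - context) : i],
                    context3=seq[i + 2 : i + 2 + context],
                )
            )
    return sites


def fold_window(target: Transcript, window: Region,
                model: EnergyModel | None = None) -> AccessibilityProfile:
    """Fold one window of the target and return its accessibility profile.

    A window too short to form any hairpin yields the degenerate profile
    (all positions unpaired with probability 1).
    """
    seq = _frame_sequence(target, window.frame)
    if window.end > len(seq):
        raise ConfigError(f"window {window} beyond sequence end ({len(seq)} nt)")
    return AccessibilityProfile(window, partition_fold(seq[window.to_slice()], model))


def window_around(target: Transcript, site: CleavageSite, size: int = 120) -> Region:
    """Folding window of ``size`` nt centred on the GU site, clipped at ends."""
    seq = _frame_sequence(target, site.frame)
    half = size // 2
    start = max(1, site.position - half)
    end = min(len(seq), start + size - 1)
    start = max(1, end - size + 1)
    return Region(target.id, start, end, frame=site.frame)


def score_site(site: CleavageSite, profile: AccessibilityProfile,
               weights: ScoreWeights = ScoreWeights(),
               p1_len: int = 8, p3_len: int = 16) -> float:
    """Weighted mean unpaired probability over the GU and both arm footprints.

    The P3 arm footprint covers the ``p3_len`` positions ending at the G,
    the P1 arm footprint the ``p1_len`` positions starting at the U; both
    are clipped at the window edges.  A fully unpaired window scores 1
    irrespective of the weights.
    """
    q = profile.unpaired_probability
    w0 = profile.window.start

    def mean_q(first: int, last: int) -> float | None:
        lo = max(first, profile.window.start) - w0
        hi = min(last, profile.window.end) - w0
        if hi < lo:
            return None
        return float(np.mean(q[lo : hi + 1]))

    p = site.position
    parts = [
        (weights.gu, mean_q(p, p + 1)),
        (weights.p3, mean_q(p - p3_len + 1, p)),
        (weights.p1, mean_q(p + 1, p + p1_len)),
    ]
    num = sum(w * v for w, v in parts if v is not None)
    den = sum(w for w, v in parts if v is not None)
    return num / den


def rank_sites(sites: list[CleavageSite]) -> list[CleavageSite]:
    """Stable sort by rank_score descending, ties broken by ascending position."""
    return sorted(sites, key=lambda s: (-(s.rank_score or 0.0), s.position))


def scan_target(target: Transcript, frame: str = "transcript",
                config: ScanConfig | None = None) -> list[CleavageSite]:
    """Full pipeline: enumerate GU sites, fold windows, score, and rank.

    Folded windows are cached on their coordinates, so sites sharing a
    clipped window do not refold it.
    """
    config = config or ScanConfig()
    sites = find_gu_sites(target, frame=frame, context=config.context)
    cache: dict[tuple[int, int], AccessibilityProfile] = {}
    scored = []
    for site in sites:
        win = window_around(target, site, config.window_size)
        key = (win.start, win.end)
        if key not in cache:
            cache[key] = fold_window(target, win, config.energy_model)
        profile = cache[key]
        score = score_site(site, profile, config.weights, config.p1_len, config.p3_len)
        acc = float(np.mean(profile.unpaired_probability[
            site.position - win.start : site.position - win.start + 2]))
        scored.append(replace(site, accessibility=acc, rank_score=score))
    return rank_sites(scored)


def binding_footprint(p1_arm: str, p3_arm: str) -> str:
    """Substrate-strand segment the two arms hybridise to, GU at the junction.

    The P3 arm binds the segment ending at the G, the P1 arm the segment
    starting at the U, so the footprint is revcomp(p3_arm) followed by
    revcomp(p1_arm).
    """
    return reverse_complement(p3_arm) + reverse_complement(p1_arm)


def off_target_scan(arms: tuple[str, str], transcriptome: list[Transcript],
                    config: OffTargetConfig | None = None) -> list[OffTargetHit]:
    """Seed-and-extend search for transcript segments matching the footprint.

    ``arms`` is ``(p1_arm, p3_arm)``.  A hit is a window identical to the
    binding footprint over an exact seed centred on the GU junction, with
    at most ``max_mismatches`` mismatches elsewhere.  ``gu_at_junction``
    reports whether the matched segment itself carries GU at the junction
    (a hit without it can only be bound, not cleaved).  Hits are ordered by
    (transcript order, position).
    """
    p1_arm, p3_arm = arms
    config = config or OffTargetConfig()
    footprint = binding_footprint(p1_arm, p3_arm)
    L = len(footprint)
    if config.seed_length > L:
        raise ConfigError(f"seed length {config.seed_length} exceeds footprint length {L}")
    g_off = len(p3_arm) - 1  # 0-based offset of the junction G in the footprint
    seed_start = min(max(0, g_off + 1 - config.seed_length // 2), L - config.seed_length)
    seed = footprint[seed_start : seed_start + config.seed_length]

    hits = []
    for t in transcriptome:
        seq = t.sequence
        pos = seq.find(seed)
        while pos != -1:
            start = pos - seed_start
            if 0 <= start <= len(seq) - L:
                segment = seq[start : start + L]
                mism = sum(a != b for a, b in zip(segment, footprint))
                if mism <= config.max_mismatches:
                    hits.append(
                        OffTargetHit(
                            transcript_id=t.id,
                            position=start + 1,
                            matched_length=L,
                            mismatches=mism,
                            gu_at_junction=segment[g_off : g_off + 2] == "GU",
                        )
                    )
            pos = seq.find(seed, pos + 1)
    return hits


def calibrate_convention(target: Transcript, positions: list[int]) -> list[tuple[str, str]]:
    """Which (frame, G-vs-U indexing) conventions make every position a GU?

    Published site lists rarely state whether positions are CDS- or
    transcript-relative, or whether they index the G or the U.  This
    checks all four conventions and returns those under which every listed
    position lands on a GU dinucleotide, as ``(frame, "G"|"U")`` tuples.
    """
    results = []
    frames = ["transcript"] + (["cds"] if target.cds is not None else [])
    for frame in frames:
        seq = _frame_sequence(target, frame)
        for anchor, offset in (("G", 0), ("U", -1)):
            if all(
                0 <= p - 1 + offset < len(seq) - 1
                and seq[p - 1 + offset : p + 1 + offset] == "GU"
                for p in positions
            ):
                results.append((frame, anchor))
    return results
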