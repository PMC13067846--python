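"""Seeded synthetic fixtures emulating the study's data regime.

Every generator here is a pure function of its arguments and seed, so
fixtures are byte-reproducible.  Defaults mirror the study conditions the
rest of the toolkit is exercised against: a CDS-like target with GU sites
planted at the four screened positions (359, 388, 427, 473), first-order
cleavage time courses around the lead rate constant (k_obs = 0.1056
min^-1 over a 0-120 min grid), gel lanes for a 46-nt substrate cut into
29 + 17 nt fragments, the published metal-dependence rate pairs, and a
log-logistic dose-response around IC50 = 137.4 nM.

Noise is additive Gaussian on fractions (or percent), clipped to the
valid range — the simplest model consistent with mean +/- SD densitometry
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError
from .kinetics import Condition, DoseResponseCurve, TimeCourse
from .seq_io import Transcript

__all__ = [
    "LEAD_KOBS_PER_MIN",
    "LEAD_IC50_NM",
    "SCREENED_POSITIONS",
    "REFERENCE_METAL_KOBS",
    "GeneratorSpec",
    "make_transcript",
    "make_transcriptome",
    "plant_offtarget",
    "simulate_timecourse",
    "simulate_gel",
    "simulate_doseresponse",
    "standin_target",
]

# Published reference values used as generator settings (lead rate constant,
# screened site positions, metal-dependence rate pairs, lead IC50).
LEAD_KOBS_PER_MIN = 0.1056
LEAD_IC50_NM = 137.4
SCREENED_POSITIONS = (359, 388, 427, 473)
#: (ion, molar concentration) -> observed k_obs in min^-1
REFERENCE_METAL_KOBS = {
    ("Mn2+", 5.0e-4): 0.1165,
    ("Mg2+", 5.0e-4): 0.0539,
    ("Mn2+", 1.56e-5): 0.0154,
    ("Mg2+", 1.56e-5): 0.0009,
}
SUBSTRATE_LENGTH_NT = 46
CUT_POSITION_NT = 29  # 5' fragment length; 3' fragment is 17 nt

_BASES = np.array(list("ACGU"))


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_transcript(length: int = 900, planted_gu: tuple[int, ...] = SCREENED_POSITIONS,
                    gc_content: float = 0.5, exclude_other_gu: bool = False,
                    seed: int | np.random.Generator = 0, transcript_id: str = "synthetic-target",
                    with_cds: bool = True) -> Transcript:
    """Random background sequence with GU dinucleotides planted at ``planted_gu``.

    Positions are 1-based indices of the planted G.  With
    ``exclude_other_gu`` every non-planted GU occurrence is removed
    (U -> C), so a scanner finds exactly the planted set.  A full-length
    CDS annotation is attached by default so both coordinate frames are
    exercised with identical positions.
    """
    rng = _rng(seed)
    planted = sorted(planted_gu)
    for a, b in zip(planted, planted[1:]):
        if b - a < 2:
            raise GenerationError(f"planted positions {a} and {b} overlap")
    if planted and (planted[0] < 1 or planted[-1] + 1 > length):
        raise GenerationError("planted positions do not fit in the stated length")
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    seq = rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    for p in planted:
        seq[p - 1], seq[p] = "G", "U"
    if exclude_other_gu:
        planted_set = set(planted)
        for i in range(length - 1):
            if seq[i] == "G" and seq[i + 1] == "U" and (i + 1) not in planted_set:
                seq[i + 1] = "C"
    return Transcript(id=transcript_id, sequence="".join(seq),
                      cds=(1, length) if with_cds else None)


def standin_target(seed: int | np.random.Generator = 0) -> Transcript:
    """Synthetic stand-in for the PD-L1 CDS target (NOT the real accession).

    A CDS-length random sequence with GU sites planted at the four screened
    positions, used wherever the workflow would scan the downloaded
    NM_021893.3 coding sequence.
    """
    return make_transcript(length=870, planted_gu=SCREENED_POSITIONS, seed=seed,
                           transcript_id="PDL1-CDS-synthetic-standin")


def make_transcriptome(n: int = 20, length: int = 1000, gc_content: float = 0.5,
                       seed: int | np.random.Generator = 1) -> list[Transcript]:
    """``n`` decoy transcripts of the given length (no planted footprints)."""
    rng = _rng(seed)
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    return [
        Transcript(id=f"decoy-{i + 1}",
                   sequence="".join(rng.choice(_BASES, size=length,
                                               p=[p_at, p_gc, p_gc, p_at])))
        for i in range(n)
    ]


def plant_offtarget(transcriptome: list[Transcript], footprint: str, index: int,
                    position: int, mismatches: int = 0, keep_junction_clear: int = 9,
                    seed: int | np.random.Generator = 2) -> list[Transcript]:
    """Embed a (possibly mutated) copy of a binding footprint in one decoy.

    ``position`` is the 1-based start.  Mutated offsets are kept more than
    ``keep_junction_clear`` positions away from the footprint centre, so a
    centred exact seed of up to ``2 * keep_junction_clear - 4`` nt can
    still find the plant (the default clears a centred 12-nt seed with
    slack for the usual 16 + 8 arm geometry).
    """
    rng = _rng(seed)
    t = transcriptome[index]
    L = len(footprint)
    if position < 1 or position + L - 1 > len(t.sequence):
        raise GenerationError("footprint does not fit at the requested position")
    fp = list(footprint)
    centre = L // 2
    candidates = [i for i in range(L) if abs(i - centre) > keep_junction_clear]
    if mismatches > len(candidates):
        raise GenerationError("not enough positions available for the requested mismatches")
    for i in sorted(rng.choice(len(candidates), size=mismatches, replace=False)):
        pos = candidates[i]
        fp[pos] = str(rng.choice([b for b in "ACGU" if b != fp[pos]]))
    seq = t.sequence[: position - 1] + "".join(fp) + t.sequence[position - 1 + L :]
    out = list(transcriptome)
    out[index] = Transcript(id=t.id, sequence=seq, cds=t.cds,
                            source_alphabet=t.source_alphabet)
    return out


#: default 13-point sampling grid, denser early where F(t) changes fastest
DEFAULT_TIME_GRID_MIN = np.array(
    [0.0, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 80.0, 100.0, 120.0])


def simulate_timecourse(k_obs: float = LEAD_KOBS_PER_MIN, plateau: float = 0.85,
                        times: np.ndarray | None = None, noise_sd: float = 0.02,
                        n_replicates: int = 3,
                        seed: int | np.random.Generator = 0,
                        condition: Condition = Condition()) -> TimeCourse:
    """First-order cleavage curve with clipped Gaussian measurement noise.

    Each reported fraction is the mean of ``n_replicates`` independent
    measurements with per-replicate standard deviation ``noise_sd``,
    emulating triplicate densitometry.
    """
    if k_obs < 0:
        raise GenerationError("k_obs must be non-negative")
    if n_replicates < 1:
        raise GenerationError("n_replicates must be at least 1")
    t = DEFAULT_TIME_GRID_MIN.copy() if times is None else np.asarray(times, dtype=float)
    f = plateau * (-np.expm1(-k_obs * t))
    if noise_sd > 0:
        reps = f + _rng(seed).normal(0.0, noise_sd, size=(n_replicates,) + t.shape)
        f = reps.mean(axis=0)
    return TimeCourse(times=t, fraction_cleaved=np.clip(f, 0.0, 1.0), condition=condition)


def simulate_gel(tc: TimeCourse, substrate_length: int = SUBSTRATE_LENGTH_NT,
                 cut_position: int = CUT_POSITION_NT, intensity_scale: float = 1000.0,
                 noise_sd: float = 0.0,
                 seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Per-lane band intensities under length-proportional staining.

    One lane per time point with substrate and two product bands whose
    intensities are (moles x length x scale) + clipped Gaussian noise.
    Inverting with ``fraction_from_bands(..., normalize_by_length=True)``
    recovers the input fractions up to the noise.
    """
    if not 0 < cut_position < substrate_length:
        raise GenerationError("cut position must fall inside the substrate")
    rng = _rng(seed)
    len5, len3 = cut_position, substrate_length - cut_position
    f = tc.fraction_cleaved
    table = pd.DataFrame({
        "time_min": tc.times,
        "substrate": (1.0 - f) * substrate_length * intensity_scale,
        "product5": f * len5 * intensity_scale,
        "product3": f * len3 * intensity_scale,
    })
    if noise_sd > 0:
        for col in ("substrate", "product5", "product3"):
            table[col] = np.clip(
                table[col] + rng.normal(0.0, noise_sd * intensity_scale, size=len(table)),
                0.0, None)
    table.attrs["lengths_nt"] = (substrate_length, len5, len3)
    return table


#: default half-log dilution series (nM) bracketing the expected IC50
DEFAULT_DOSE_SERIES_NM = np.array(
    [1.0, 3.16, 10.0, 31.6, 100.0, 316.0, 1000.0, 3160.0, 10000.0])


def simulate_doseresponse(ic50: float = LEAD_IC50_NM, hill: float = 1.0,
                          top: float = 85.0, bottom: float = 5.0,
                          concentrations: np.ndarray | None = None,
                          noise_sd: float = 3.0, n_replicates: int = 3,
                          seed: int | np.random.Generator = 0) -> DoseResponseCurve:
    """Log-logistic percent-inhibition curve over a half-log dilution series.

    Each response is the mean of ``n_replicates`` measurements with
    per-replicate standard deviation ``noise_sd`` percentage points,
    emulating a triplicate knockdown assay; the replicate SD is attached.
    """
    if hill == 0:
        raise GenerationError("hill slope of zero gives a flat, non-identifiable curve")
    if ic50 <= 0:
        raise GenerationError("ic50 must be positive")
    if n_replicates < 1:
        raise GenerationError("n_replicates must be at least 1")
    c = (DEFAULT_DOSE_SERIES_NM.copy()
         if concentrations is None else np.asarray(concentrations, dtype=float))
    r = bottom + (top - bottom) / (1.0 + (ic50 / c) ** hill)
    sd = None
    if noise_sd > 0:
        reps = r + _rng(seed).normal(0.0, noise_sd, size=(n_replicates,) + c.shape)
        r = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1) if n_replicates > 1 else None
    return DoseResponseCurve(concentrations=c, response=np.clip(r, 0.0, 100.0),
                             replicate_sd=sd)


@dataclass(frozen=True)
class GeneratorSpec:
    """Bundle of generator settings; identical specs give identical fixtures."""

    seed: int = 0
    transcript_length: int = 900
    planted_sites: tuple[int, ...] = SCREENED_POSITIONS
    gc_content: float = 0.5
    n_decoys: int = 20
    decoy_length: int = 1000
    k_obs: float = LEAD_KOBS_PER_MIN
    plateau: float = 0.85
    kinetic_noise_sd: float = 0.02
    ic50: float = LEAD_IC50_NM
    hill: float = 1.0
    top: float = 85.0
    bottom: float = 5.0
    dose_noise_sd: float = 3.0

    def transcript(self) -> Transcript:
        return make_transcript(self.transcript_length, self.planted_sites,
                               self.gc_content, seed=self.seed)

    def transcriptome(self) -> list[Transcript]:
        return make_transcriptome(self.n_decoys, self.decoy_length,
                                  self.gc_content, seed=self.seed + 1)

    def timecourse(self) -> TimeCourse:
        return simulate_timecourse(self.k_obs, self.plateau,
                                   noise_sd=self.kinetic_noise_sd, seed=self.seed + 2)

    def doseresponse(self) -> DoseResponseCurve:
        return simulate_doseresponse(self.ic50, self.hill, self.top, self.bottom,
                                     noise_sd=self.dose_noise_sd, seed=self.seed + 3)
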