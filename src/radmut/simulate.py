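"""Synthetic data with the statistical structure the pipeline assumes.

Generates a toy reference genome, spikes per-plant mutation events drawn
from per-strain profiles (event rates, SBS spectrum, InDel lengths,
deletion-junction microhomology bias, complex-event composition), draws
zygosity from Mendelian M2 segregation, emits caller-style candidate
tables (VCF + sv_tsv) with read-support allele frequencies, low-AF noise
and multi-sample artifact sites, and simulates seed-survival assays from
the single-hit multitarget curve.

The default strain profiles mirror the per-plant event counts reported
for gamma-irradiated Arabidopsis wild type (1000 Gy) and the
NHEJ-deficient AtKu70-/- and AtLig4-/- mutants (100 Gy): events are
placed on a small toy genome at those per-plant counts rather than at
genome-scaled per-bp rates, which keeps desk-scale runs fast while
preserving every per-plant statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as rio
from .events import Category, MutationEvent, build_events
from .genome import ReferenceGenome
from .microhomology import MH_BINS, bin_microhomology, compute_microhomology
from .reference_tables import RATE_PER_BP_X1E8, STRAIN_DOSES_GY
from .survival import SurvivalObservation, multitarget_survival
from .variants import CandidateCall, FilteredCall, VariantClass, normalize_variant

_BASES = np.array(list("ACGT"))

# placement padding keeps independently generated events more than one
# merge window apart and leaves room for left-alignment shifts
_PAD_BP = 30


def generate_reference(
    length_bp: int, gc_fraction: float = 0.36, seed: int = 0, n_chroms: int = 1
) -> ReferenceGenome:
    """Random genome with the given GC content (i.i.d. bases, no N)."""
    if length_bp < 1000:
        raise ValueError("length_bp must be >= 1000")
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    per = length_bp // n_chroms
    seqs = {}
    for i in range(n_chroms):
        n = per if i < n_chroms - 1 else length_bp - per * (n_chroms - 1)
        seqs[f"chr{i + 1}"] = "".join(rng.choice(_BASES, size=n, p=p))
    return ReferenceGenome(seqs)


@dataclass
class StrainProfile:
    """Per-strain generating parameters for the mutation simulator."""

    name: str
    dose_gy: float
    event_rates: dict[str, float]           # per-plant Poisson means by category
    sbs_weights: dict[str, float]           # over the 6 strand-collapsed classes
    del_length_weights: dict[str, float]    # Del >= 2 bp length bins
    ins_length_weights: dict[str, float]    # Ins >= 2 bp length bins
    mh_target: dict[str, float]             # deletion microhomology bins
    complex_sbs_only: float                 # P(complex event is SBS-only)

    def __post_init__(self) -> None:
        for w in (
            self.sbs_weights,
            self.del_length_weights,
            self.ins_length_weights,
            self.mh_target,
        ):
            total = sum(w.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"weights sum to {total}, expected 1")
        if any(r < 0 for r in self.event_rates.values()):
            raise ValueError("event rates must be >= 0")


_SBS_WEIGHTS = {
    "A/T>G/C": 0.22,
    "G/C>A/T": 0.22,
    "A/T>T/A": 0.20,
    "A/T>C/G": 0.12,
    "G/C>T/A": 0.12,
    "G/C>C/G": 0.12,
}

_LEN_BINS = ("2-10", "11-30", "31-100", ">100")
_WT_DEL_LEN = {"2-10": 0.60, "11-30": 0.25, "31-100": 0.10, ">100": 0.05}
_MUT_DEL_LEN = {"2-10": 0.20, "11-30": 0.50, "31-100": 0.22, ">100": 0.08}
_WT_INS_LEN = {"2-10": 0.70, "11-30": 0.20, "31-100": 0.08, ">100": 0.02}

# the >= 10 bp bin gets weight 0: an i.i.d. random toy genome has no long
# repeats, so junctions with >= 10 bp of flank identity essentially never
# exist to be sampled (real genomes reach that bin through repeat families)
_WT_MH = {"0": 0.24, "1": 0.18, "2": 0.30, "3-4": 0.18, "5-9": 0.10, ">=10": 0.0}
_KU70_MH = {"0": 0.12, "1": 0.12, "2": 0.22, "3-4": 0.34, "5-9": 0.20, ">=10": 0.0}
_LIG4_MH = {"0": 0.04, "1": 0.13, "2": 0.21, "3-4": 0.40, "5-9": 0.22, ">=10": 0.0}


def _profile_from_table(
    strain: str, mh: dict[str, float], del_len: dict[str, float], sbs_only: float
) -> StrainProfile:
    row = RATE_PER_BP_X1E8.loc[strain]
    return StrainProfile(
        name=strain,
        dose_gy=STRAIN_DOSES_GY[strain],
        event_rates={
            c.value: float(row[c.value])
            for c in (
                Category.SBS,
                Category.DEL1,
                Category.INS1,
                Category.DEL_GE2,
                Category.INS_GE2,
                Category.COMPLEX,
                Category.SV,
            )
        },
        sbs_weights=dict(_SBS_WEIGHTS),
        del_length_weights=dict(del_len),
        ins_length_weights=dict(_WT_INS_LEN),
        mh_target=dict(mh),
        complex_sbs_only=sbs_only,
    )


def wt_profile() -> StrainProfile:
    return _profile_from_table("WT", _WT_MH, _WT_DEL_LEN, 20 / 23)


def atku70_profile() -> StrainProfile:
    return _profile_from_table("AtKu70", _KU70_MH, _MUT_DEL_LEN, 4 / 27)


def atlig4_profile() -> StrainProfile:
    return _profile_from_table("AtLig4", _LIG4_MH, _MUT_DEL_LEN, 4 / 27)


DEFAULT_PROFILES = {"WT": wt_profile, "AtKu70": atku70_profile, "AtLig4": atlig4_profile}


@dataclass
class GroundTruth:
    """True spiked events per plant, plus the generating parameters."""

    profile: StrainProfile
    seed: int
    plants: dict[str, list[MutationEvent]] = field(default_factory=dict)

    @property
    def all_events(self) -> list[MutationEvent]:
        return [e for evs in self.plants.values() for e in evs]


def simulate_m2(n_m1_mutations: int, seed: int = 0) -> np.ndarray:
    """M2 states of M1-heterozygous mutations in one sampled selfed plant.

    Mendelian segregation gives homozygous with probability 1/4,
    heterozygous 1/2, absent 1/4 — hence hom:het = 0.5 among carriers.
    """
    if n_m1_mutations < 1:
        raise ValueError("need at least one mutation")
    rng = np.random.default_rng(seed)
    return rng.choice(
        np.array(["homozygous", "heterozygous", "absent"]),
        size=n_m1_mutations,
        p=[0.25, 0.5, 0.25],
    )


def _sample_weighted(rng, weights: dict[str, float]) -> str:
    keys = list(weights)
    return keys[rng.choice(len(keys), p=np.array([weights[k] for k in keys]))]


def _length_from_bin(rng, label: str) -> int:
    lo, hi = {"2-10": (2, 10), "11-30": (11, 30), "31-100": (31, 100), ">100": (101, 300)}[
        label
    ]
    return int(rng.integers(lo, hi + 1))


class _Placer:
    """Tracks reserved intervals per chromosome to keep events apart."""

    def __init__(self, ref: ReferenceGenome, pad: int = _PAD_BP):
        self.ref = ref
        self.pad = pad
        self.reserved: dict[str, list[tuple[int, int]]] = {
            c: [] for c in ref.sequences
        }

    def try_reserve(self, chrom: str, start: int, end: int) -> bool:
        if start - self.pad < 1 or end + self.pad > self.ref.chrom_length(chrom):
            return False
        s, e = start - self.pad, end + self.pad
        for a, b in self.reserved[chrom]:
            if s <= b and a <= e:
                return False
        self.reserved[chrom].append((s, e))
        return True


def _random_site(rng, ref: ReferenceGenome, span: int) -> tuple[str, int]:
    chroms = list(ref.sequences)
    lens = np.array([ref.chrom_length(c) for c in chroms], dtype=float)
    chrom = chroms[rng.choice(len(chroms), p=lens / lens.sum())]
    pos = int(rng.integers(_PAD_BP + 1, ref.chrom_length(chrom) - span - _PAD_BP))
    return chrom, pos


def _sbs_call(rng, ref, profile, sample, chrom=None, pos=None) -> CandidateCall:
    cls = _sample_weighted(rng, profile.sbs_weights)
    for _ in range(10000):
        ref_pair = cls[0] + cls[2]  # e.g. "A/T>G/C" -> bases A or T
        if chrom is None or pos is None:
            c, p = _random_site(rng, ref, 1)
        else:
            c, p = chrom, pos
        base = ref.base(c, p)
        if base in ref_pair:
            alt = cls[4] if base == cls[0] else cls[6]
            return CandidateCall(
                sample, c, p, base, alt, VariantClass.SUBSTITUTION, 1.0, source="truth"
            )
        if chrom is not None:  # fixed position: flip the class to fit the base
            cls = (
                "A/T>G/C" if base in "AT" else "G/C>A/T"
            )
    raise RuntimeError("could not place SBS")  # pragma: no cover


def _deletion_call(
    rng, ref, profile, sample, placer, length: int, target_bin: str | None, max_tries=1000
) -> CandidateCall | None:
    """Deletion placed by rejection sampling toward the target mh bin."""
    fallback = None
    for _ in range(max_tries):
        chrom, start = _random_site(rng, ref, length)
        end = start + length - 1
        mh = compute_microhomology(ref, chrom, start, end)
        if mh is None:
            continue
        call = CandidateCall(
            sample,
            chrom,
            start,
            ref.fetch(chrom, start, end),
            "",
            VariantClass.DELETION,
            1.0,
            source="truth",
        )
        if target_bin is None or bin_microhomology(mh) == target_bin:
            if placer.try_reserve(chrom, start, end):
                return normalize_variant(call, ref)
        elif fallback is None:
            fallback = call
    if fallback is not None and placer.try_reserve(
        fallback.chrom, fallback.pos, fallback.pos + length - 1
    ):
        return normalize_variant(fallback, ref)
    return None


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def spike_mutations(
    ref: ReferenceGenome, profile: StrainProfile, n_plants: int, seed: int = 0
) -> GroundTruth:
    """Draw per-plant mutation events from the profile onto the genome.

    Per-type counts are Poisson around the profile rates; deletion
    endpoints are rejection-sampled toward the target microhomology-bin
    distribution; complex events are built as >= 2 variants within the
    merge window; zygosity is drawn at the detected-M2 Mendelian odds
    (1/3 homozygous, 2/3 heterozygous).
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth(profile=profile, seed=seed)
    for i in range(n_plants):
        sample = f"{profile.name}_p{i + 1:02d}"
        placer = _Placer(ref)
        calls: list[FilteredCall] = []

        def zygosity() -> str:
            return "homozygous" if rng.random() < 1.0 / 3.0 else "heterozygous"

        def add(call_group: list[CandidateCall]) -> None:
            zyg = zygosity()
            af = 1.0 if zyg == "homozygous" else 0.5
            norm = [normalize_variant(c, ref) for c in call_group]
            spans = sorted(c.span for c in norm)
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                if s2 <= e1:  # left-alignment slid a member into its neighbour
                    norm = call_group
                    break
            for c in norm:
                calls.append(
                    FilteredCall(
                        **{
                            **c.__dict__,
                            "allele_frequency": af,
                            "zygosity": zyg,
                        }
                    )
                )

        n_by_type = {
            cat: int(rng.poisson(rate)) for cat, rate in profile.event_rates.items()
        }

        for _ in range(n_by_type.get("SBS", 0)):
            for _ in range(1000):
                c = _sbs_call(rng, ref, profile, sample)
                if placer.try_reserve(c.chrom, c.pos, c.pos):
                    add([c])
                    break

        for _ in range(n_by_type.get("Del1", 0)):
            for _ in range(1000):
                chrom, pos = _random_site(rng, ref, 1)
                if placer.try_reserve(chrom, pos, pos):
                    call = CandidateCall(
                        sample, chrom, pos, ref.base(chrom, pos), "",
                        VariantClass.DELETION, 1.0, source="truth",
                    )
                    add([normalize_variant(call, ref)])
                    break

        for _ in range(n_by_type.get("Ins1", 0)):
            for _ in range(1000):
                chrom, pos = _random_site(rng, ref, 1)
                if placer.try_reserve(chrom, pos, pos + 1):
                    call = CandidateCall(
                        sample, chrom, pos, "", _random_seq(rng, 1),
                        VariantClass.INSERTION, 1.0, source="truth",
                    )
                    add([normalize_variant(call, ref)])
                    break

        for _ in range(n_by_type.get("DelGE2", 0)):
            length = _length_from_bin(
                rng, _sample_weighted(rng, profile.del_length_weights)
            )
            target = _sample_weighted(rng, profile.mh_target)
            c = _deletion_call(rng, ref, profile, sample, placer, length, target)
            if c is not None:
                add([c])

        for _ in range(n_by_type.get("InsGE2", 0)):
            length = _length_from_bin(
                rng, _sample_weighted(rng, profile.ins_length_weights)
            )
            for _ in range(1000):
                chrom, pos = _random_site(rng, ref, 1)
                if placer.try_reserve(chrom, pos, pos + 1):
                    call = CandidateCall(
                        sample, chrom, pos, "", _random_seq(rng, length),
                        VariantClass.INSERTION, 1.0, source="truth",
                    )
                    add([normalize_variant(call, ref)])
                    break

        for _ in range(n_by_type.get("Complex", 0)):
            sbs_only = rng.random() < profile.complex_sbs_only
            n_members = int(rng.integers(2, 4))
            gaps = [int(rng.integers(2, 9)) for _ in range(n_members - 1)]
            span_guess = 3 * n_members + sum(gaps) + 10
            for _ in range(1000):
                chrom, start = _random_site(rng, ref, span_guess)
                if not placer.try_reserve(chrom, start, start + span_guess):
                    continue
                group: list[CandidateCall] = []
                pos = start
                for j in range(n_members):
                    if sbs_only or j == 0:
                        c = _sbs_call(rng, ref, profile, sample, chrom, pos)
                        group.append(c)
                        pos = pos + 1 + gaps[j] if j < n_members - 1 else pos
                    else:
                        dlen = int(rng.integers(2, 6))
                        c = CandidateCall(
                            sample, chrom, pos, ref.fetch(chrom, pos, pos + dlen - 1),
                            "", VariantClass.DELETION, 1.0, source="truth",
                        )
                        group.append(c)
                        pos = pos + dlen + gaps[j] if j < n_members - 1 else pos
                add(group)
                break

        for _ in range(n_by_type.get("SV", 0)):
            span = int(rng.integers(500, 5001))
            for _ in range(1000):
                chrom, start = _random_site(rng, ref, span)
                if placer.try_reserve(chrom, start, start + span - 1):
                    vclass = (
                        VariantClass.INVERSION
                        if rng.random() < 0.7
                        else VariantClass.TRANSLOCATION
                    )
                    add(
                        [
                            CandidateCall(
                                sample, chrom, start, "", "", vclass, 1.0,
                                source="truth", end=start + span - 1,
                            )
                        ]
                    )
                    break

        truth.plants[sample] = build_events(calls, ref)
    return truth


def emit_candidate_calls(
    truth: GroundTruth,
    ref: ReferenceGenome,
    depth: float | None = 50.0,
    error_rate: float = 0.0,
    n_artifact_sites: int = 0,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> dict[str, list[CandidateCall]]:
    """Caller-style candidate tables from the ground truth.

    ``depth=None`` emits noise-free allele frequencies (exactly 0.5 / 1.0);
    otherwise per-site depth is Poisson around ``depth`` and mutant reads
    binomial at the true allele fraction. ``error_rate`` is the expected
    number of low-AF (<= 0.25) noise substitution calls per plant;
    ``n_artifact_sites`` shared sites are injected into > 2 samples so
    the cross-sample filter has something to remove. When ``outdir`` is
    given, per-sample VCF + sv_tsv files, a truth event table and a
    metadata JSON (including seeds) are written.
    """
    rng = np.random.default_rng(seed)
    samples = sorted(truth.plants)
    emitted: dict[str, list[CandidateCall]] = {s: [] for s in samples}

    for sample in samples:
        for event in truth.plants[sample]:
            for m in event.members:
                p_true = 1.0 if m.zygosity == "homozygous" else 0.5
                if depth is None:
                    af = p_true
                else:
                    d = max(1, int(rng.poisson(depth)))
                    af = rng.binomial(d, p_true) / d
                emitted[sample].append(
                    CandidateCall(
                        **{
                            **{
                                k: v
                                for k, v in m.__dict__.items()
                                if k != "zygosity"
                            },
                            "allele_frequency": float(af),
                            "source": "caller",
                        }
                    )
                )
        n_noise = int(rng.poisson(error_rate)) if error_rate > 0 else 0
        for _ in range(n_noise):
            chrom, pos = _random_site(rng, ref, 1)
            base = ref.base(chrom, pos)
            alt = str(rng.choice([b for b in "ACGT" if b != base]))
            emitted[sample].append(
                CandidateCall(
                    sample, chrom, pos, base, alt, VariantClass.SUBSTITUTION,
                    float(rng.uniform(0.01, 0.25)), source="noise",
                )
            )

    for _ in range(n_artifact_sites):
        chrom, pos = _random_site(rng, ref, 1)
        base = ref.base(chrom, pos)
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        carriers = rng.choice(
            len(samples), size=min(len(samples), max(3, len(samples) // 2)), replace=False
        )
        for idx in carriers:
            s = samples[idx]
            emitted[s].append(
                CandidateCall(
                    s, chrom, pos, base, alt, VariantClass.SUBSTITUTION,
                    float(rng.uniform(0.3, 0.6)), source="artifact",
                )
            )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rio.write_fasta(ref, outdir / "reference.fa")
        for s in samples:
            small = [c for c in emitted[s] if not c.is_sv]
            svs = [c for c in emitted[s] if c.is_sv]
            rio.write_vcf(small, ref, outdir / f"{s}.vcf", sample_id=s)
            rio.write_sv_tsv(svs, outdir / f"{s}.sv.tsv")
        rio.write_event_table(truth.all_events, outdir / "truth_events.tsv", ref)
        meta = {
            "profile": truth.profile.name,
            "dose_gy": truth.profile.dose_gy,
            "spike_seed": truth.seed,
            "emit_seed": seed,
            "depth": depth,
            "error_rate": error_rate,
            "n_artifact_sites": n_artifact_sites,
            "samples": samples,
        }
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
    return emitted


def simulate_survival(
    d0_gy: float,
    n_extrapolation: float,
    doses: list[float],
    n_plants: int = 30,
    n_reps: int = 3,
    seed: int = 0,
) -> list[SurvivalObservation]:
    """Binomial seed-survival assay from the multitarget curve."""
    if d0_gy <= 0 or n_extrapolation < 1:
        raise ValueError("require d0_gy > 0 and n_extrapolation >= 1")
    rng = np.random.default_rng(seed)
    obs = []
    for dose in doses:
        s = float(multitarget_survival(dose, d0_gy, n_extrapolation))
        for rep in range(n_reps):
            obs.append(
                SurvivalObservation(
                    dose_gy=float(dose),
                    n_sown=n_plants,
                    n_survived=int(rng.binomial(n_plants, s)),
                    replicate=str(rep + 1),
                )
            )
    return obs
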