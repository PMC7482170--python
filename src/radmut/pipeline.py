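"""End-to-end orchestration: simulate, filter, classify, summarize, fit.

Every intermediate artifact is a plain TSV with a header so each stage
can be inspected and diffed; the run log records the exact thresholds
and seeds used plus call counts at every filter stage, and contains no
timestamps so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as rio
from .events import Category, build_events
from .filtering import FilterConfig, filter_calls
from .genome import ReferenceGenome
from .microhomology import junction_from_deletion, microhomology_distribution
from .simulate import (
    DEFAULT_PROFILES,
    emit_candidate_calls,
    generate_reference,
    simulate_survival,
    spike_mutations,
)
from .spectra import (
    StrainSummary,
    fold_change,
    indel_length_distribution,
    sbs_spectrum,
    summarize_strain,
    zygosity_ratio,
)
from .survival import SingleHitMultiTargetModel


@dataclass
class StrainRunConfig:
    profile: str              # one of the built-in profiles
    n_plants: int = 5
    # survival-assay generating parameters (single-hit multitarget)
    survival_d0_gy: float = 200.0
    survival_n: float = 3.0
    survival_doses: list[float] = field(
        default_factory=lambda: [0, 50, 100, 150, 200, 250, 300, 350]
    )


@dataclass
class RunConfig:
    outdir: str = "radmut_out"
    seed: int = 0
    genome_length_bp: int = 1_000_000
    gc_fraction: float = 0.36
    depth: float | None = 50.0
    error_rate: float = 2.0
    n_artifact_sites: int = 3
    merge_window_bp: int = 10
    filter: FilterConfig = field(default_factory=FilterConfig)
    strains: dict[str, StrainRunConfig] = field(
        default_factory=lambda: {
            "WT": StrainRunConfig(
                "WT", 5, survival_d0_gy=1862.0, survival_n=3.0,
                survival_doses=[0, 400, 800, 1200, 1600, 2000, 2500, 3000],
            ),
            "AtKu70": StrainRunConfig("AtKu70", 5, survival_d0_gy=176.0),
            "AtLig4": StrainRunConfig("AtLig4", 5, survival_d0_gy=202.0),
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        strains = {
            name: StrainRunConfig(**sc) for name, sc in raw.pop("strains", {}).items()
        }
        filt = FilterConfig(**raw.pop("filter", {}))
        cfg = cls(**raw, filter=filt)
        if strains:
            cfg.strains = strains
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> filter -> classify -> summarize -> survival fit.

    Returns a report dict (summaries, fold changes, fits) and writes all
    stage TSVs plus ``run_log.txt`` under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"radmut {__version__}",
        f"seed: {config.seed}",
        f"genome: {config.genome_length_bp} bp, GC {config.gc_fraction}",
        f"filter thresholds: AF-exclusion <= {config.filter.af_exclusion_max}, "
        f"heterozygous if AF < {config.filter.het_hom_boundary} (homozygous if >=), "
        f"other-sample AF < {config.filter.other_sample_max}, "
        f"shared-site samples > {config.filter.shared_site_max_samples} excluded",
        f"merge window: {config.merge_window_bp} bp",
    ]

    ref = generate_reference(
        config.genome_length_bp, config.gc_fraction, seed=config.seed
    )
    rio.write_fasta(ref, out / "reference.fa")

    summaries: dict[str, StrainSummary] = {}
    report: dict = {"summaries": summaries, "survival": {}}
    spectra_frames = []
    length_frames = []
    mh_rows = []

    for idx, (strain, sc) in enumerate(sorted(config.strains.items())):
        profile = DEFAULT_PROFILES[sc.profile]()
        spike_seed = config.seed * 1000 + idx * 17 + 1
        truth = spike_mutations(ref, profile, sc.n_plants, seed=spike_seed)
        emitted = emit_candidate_calls(
            truth,
            ref,
            depth=config.depth,
            error_rate=config.error_rate,
            n_artifact_sites=config.n_artifact_sites,
            seed=spike_seed + 7,
            outdir=out / f"calls_{strain}",
        )

        all_calls = [c for calls in emitted.values() for c in calls]
        result = filter_calls(all_calls, config.filter)
        log.append(
            f"{strain}: candidates {result.n_input} -> "
            + ", ".join(f"{k} {v}" for k, v in result.counts().items())
        )

        by_plant: dict[str, list] = {s: [] for s in emitted}
        for c in result.retained:
            by_plant[c.sample_id].append(c)
        events_by_plant = {
            s: build_events(calls, ref, config.merge_window_bp)
            for s, calls in by_plant.items()
        }
        all_events = [e for evs in events_by_plant.values() for e in evs]
        rio.write_event_table(all_events, out / f"events_{strain}.tsv", ref)

        summary = summarize_strain(
            events_by_plant, strain, profile.dose_gy, ref.total_length
        )
        summaries[strain] = summary
        summary.counts.to_csv(out / f"counts_{strain}.tsv", sep="\t")
        summary.to_frame().to_csv(out / f"summary_{strain}.tsv", sep="\t")

        zr = zygosity_ratio(all_events)
        log.append(
            f"{strain}: zygosity hom {zr.n_homozygous} / het {zr.n_heterozygous}"
            f" (ratio {zr.ratio if zr.ratio is not None else 'NA'})"
        )

        spec = sbs_spectrum(all_events)
        spectra_frames.append(pd.Series(spec, name=strain))
        length_frames.append(
            indel_length_distribution(all_events).add_prefix(f"{strain}_")
        )

        junctions = [
            junction_from_deletion(ref, e.chrom, e.start, e.end)
            for e in all_events
            if e.category is Category.DEL_GE2
        ]
        dist = microhomology_distribution(junctions)
        for b, frac in dist.fractions.items():
            mh_rows.append(
                {
                    "strain": strain,
                    "bin": b,
                    "count": dist.counts[b],
                    "fraction": frac,
                }
            )

        # survival assay simulated from the strain's generating curve
        obs = simulate_survival(
            sc.survival_d0_gy,
            sc.survival_n,
            sc.survival_doses,
            seed=spike_seed + 13,
        )
        fit = SingleHitMultiTargetModel.from_observations(obs).fit()
        report["survival"][strain] = fit
        pd.DataFrame(
            [
                {
                    "strain": strain,
                    "d0_gy": fit.d0_gy,
                    "n_extrapolation": fit.n_extrapolation,
                    "dq_gy": fit.dq_gy,
                    "se_d0_gy": fit.bse["d0_gy"],
                    "se_n": fit.bse["n_extrapolation"],
                    "se_dq_gy": fit.bse["dq_gy"],
                    "rss": fit.rss,
                }
            ]
        ).to_csv(out / f"survival_fit_{strain}.tsv", sep="\t", index=False)
        fit.curve_table().to_csv(
            out / f"survival_curve_{strain}.tsv", sep="\t", index=False
        )
        log.append(
            f"{strain}: survival fit D0 {fit.d0_gy:.1f} Gy, "
            f"n {fit.n_extrapolation:.2f}, Dq {fit.dq_gy:.1f} Gy"
        )

    pd.concat(spectra_frames, axis=1).to_csv(out / "sbs_spectrum.tsv", sep="\t")
    pd.concat(length_frames, axis=1).to_csv(out / "indel_lengths.tsv", sep="\t")
    pd.DataFrame(mh_rows).to_csv(out / "microhomology.tsv", sep="\t", index=False)

    wt = summaries.get("WT")
    if wt is not None and len(summaries) > 1:
        mutants = [s for name, s in summaries.items() if name != "WT"]
        folds = {
            cat.value: fold_change(mutants, wt, cat.value)
            for cat in Category
        }
        folds["Total"] = fold_change(mutants, wt, "Total")
        report["fold_changes"] = folds
        pd.Series(folds, name="fold_change_vs_WT_per_Gy").to_csv(
            out / "fold_changes.tsv", sep="\t"
        )
        log.append(
            "fold changes per Gy vs WT: "
            + ", ".join(
                f"{k} {v:.2f}" for k, v in folds.items() if not math.isnan(v)
            )
        )

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    report["log"] = log
    return report


def config_to_yaml(config: RunConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
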