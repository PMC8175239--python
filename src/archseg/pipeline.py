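"""End-to-end pipeline: simulate (or load) -> call segments -> date -> report.

One global seed is forked deterministically per stage via
``numpy.random.SeedSequence``, so identical config gives identical
outputs and the JSON manifest written next to the results suffices to
reproduce any run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import admix_dating, ascertainment, segment_hmm, synthetic_data
from .io_formats import read_genetic_map, write_genetic_map, write_segments_bed

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every stage parameter of a pipeline run, serialized into the manifest."""

    # simulation
    generations: float = 74.0
    proportion: float = 0.032
    n_chrom: int = 30
    chrom_cM: float = 115.0
    n_anchors: int = 200
    rate_variability: float = 0.3
    site_density_per_cM: float = 100.0
    p_archaic_given_N: float = 0.5
    p_archaic_given_H: float = 0.01
    missing_rate: float = 0.0
    # HMM
    baum_welch_iter: int = 8
    baum_welch_tol: float = 1e-4
    min_posterior: float = 0.8
    min_sites: int = 3
    # dating
    k_top: int = 100
    n_boot: int = 500
    decay_bin_width_cM: float = 0.05
    decay_min_cM: float = 0.05
    decay_max_cM: float = 2.0
    # run control
    seed: int = 1
    out_dir: str = "archseg_run"
    map_path: str | None = None    # use an existing map instead of simulating
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Parse a plain-text ``key = value`` config file."""
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                default = getattr(cls, key, None)
                if isinstance(default, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(default, int) and not isinstance(default, bool):
                    kwargs[key] = int(value)
                elif isinstance(default, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = None if value.lower() == "none" else value
        return cls(**kwargs)


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


@dataclass
class PipelineReport:
    config: RunConfig
    carriage: ascertainment.CarriageSummary
    n_segments: int
    top_k_mean_cM: float
    date_top: admix_dating.AdmixtureDate
    date_decay: admix_dating.AdmixtureDate
    truth_generations: float | None = None
    fitted_params: segment_hmm.HmmParams | None = None
    outputs: dict[str, str] = field(default_factory=dict)

    def summary_table(self) -> str:
        """Human- and machine-readable TSV summary."""
        rows = [
            ("n_ascertained", self.carriage.n_ascertained),
            ("n_covered", self.carriage.n_covered),
            ("n_archaic_allele", self.carriage.n_archaic_allele),
            ("percent_archaic", self.carriage.percent_archaic),
            ("n_segments", self.n_segments),
            ("top_k_mean_cM", round(self.top_k_mean_cM, 6)),
            ("generations_top_segments", round(self.date_top.generations, 4)),
            ("ci_low_top", round(self.date_top.interval[0], 4)),
            ("ci_high_top", round(self.date_top.interval[1], 4)),
            ("generations_state_decay", round(self.date_decay.generations, 4)),
            ("se_state_decay", round(self.date_decay.se, 4)
             if self.date_decay.se is not None else ""),
        ]
        if self.truth_generations is not None:
            rows.append(("truth_generations", self.truth_generations))
            rows.append(("delta_top_segments",
                         round(self.date_top.generations - self.truth_generations, 4)))
            rows.append(("delta_state_decay",
                         round(self.date_decay.generations - self.truth_generations, 4)))
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute simulate -> call -> date and write outputs + manifest.

    A stage failure aborts with the failing stage named; files already
    written are renamed with a ``.partial`` suffix.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["map", "tracts", "calls", "dating"])
    outputs: dict[str, str] = {}
    stage = "setup"
    try:
        stage = "simulate-map"
        if config.map_path:
            if not Path(config.map_path).exists():
                raise FileNotFoundError(f"map file {config.map_path!r} not found")
            gmap = read_genetic_map(config.map_path)
        else:
            gmap = synthetic_data.simulate_map(
                config.n_chrom, config.chrom_cM, config.n_anchors,
                config.rate_variability, seed=seeds["map"])
            write_genetic_map(gmap, str(out / "map.txt"))
            outputs["map"] = str(out / "map.txt")

        stage = "simulate-genome"
        truth = synthetic_data.simulate_admixed_diploid(
            gmap, config.generations, config.proportion, seed=seeds["tracts"])
        sites, calls = synthetic_data.simulate_calls(
            truth, config.site_density_per_cM, config.p_archaic_given_N,
            config.p_archaic_given_H, config.missing_rate, seed=seeds["calls"])
        sites_path = out / "sites.tsv"
        sites.assign(call=calls).to_csv(sites_path, sep="\t", index=False)
        outputs["sites"] = str(sites_path)

        stage = "carriage"
        carriage = ascertainment.summarize_carriage(sites, calls)

        stage = "fit-hmm"
        background = segment_hmm.estimate_background_rate(calls)
        init = segment_hmm.HmmParams.from_admixture(
            proportion=config.proportion,
            p_archaic_given_N=config.p_archaic_given_N,
            p_archaic_given_H=background)
        fitted = segment_hmm.fit_params_baumwelch(
            sites, calls, gmap, init,
            max_iter=config.baum_welch_iter, tol=config.baum_welch_tol)

        stage = "call-segments"
        segments = segment_hmm.decode_segments(
            sites, calls, gmap, fitted, config.min_posterior, config.min_sites)
        admix_dating.genetic_lengths(segments, gmap)
        bed_path = out / "segments.bed"
        write_segments_bed(segments, str(bed_path))
        outputs["segments"] = str(bed_path)

        stage = "date-top-segments"
        date_top = admix_dating.date_from_top_segments(
            segments, k=config.k_top, n_boot=config.n_boot,
            rng_seed=seeds["dating"], map_name=gmap.name)
        top = sorted((s.length_cM for s in segments), reverse=True)[:config.k_top]

        stage = "date-decay"
        curve = admix_dating.state_decay_curve(
            sites, calls, gmap, config.decay_bin_width_cM,
            config.decay_max_cM, config.decay_min_cM)
        date_decay = admix_dating.fit_decay(curve, rng_seed=seeds["dating"],
                                            map_name=gmap.name)

        stage = "report"
        report = PipelineReport(
            config=config, carriage=carriage, n_segments=len(segments),
            top_k_mean_cM=float(np.mean(top)), date_top=date_top,
            date_decay=date_decay, truth_generations=config.generations,
            fitted_params=fitted, outputs=outputs)
        (out / "summary.tsv").write_text(report.summary_table())
        manifest = {
            "config": asdict(config),
            "stage_seeds": seeds,
            "outputs": outputs,
            "fitted_params": asdict(fitted),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return report
    except Exception as exc:
        for path in outputs.values():
            p = Path(path)
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
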