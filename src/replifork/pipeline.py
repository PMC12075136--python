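"""End-to-end orchestration: config -> binned profiles -> correction -> fit
-> fork-speed report.

The run configuration is a plain nested mapping (usually loaded from YAML):

.. code-block:: yaml

    strain:
      preset: mg1655_oriCX      # or mg1655; explicit fields override
    bin_size: 1000
    correction_window: 30
    mapq_min: 20
    mask_low_quantile: 0.001
    mask_high_quantile: 0.999
    peak_window: 20000
    seed: 1
    samples:                    # external inputs ...
      - id: S1
        counts: s1_bins.tsv     # or  alignment: s1.sam
        tau: 3600               # seconds; or tau_minutes, or od_series: s1_od.csv
    simulate:                   # ... or a simulator block instead of files
      n_samples: 2
      tau: 3600
      initiation_age: 60
      speeds: {v4: 0.5, v2: 0.8, v1: 1.0}   # kbp/s; or  constant: 1.0
      failure_fraction: 0.0
      failure_split: 0.5
      depth: 10000000
      bias_log2_sigma: 0.0
      shared_bias: true
      noise: poisson

Every stage logs its parameters; numeric outputs are deterministic given
the same configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, RepliforkError
from .genome import StrainConfig, build_segments
from .metrics import analyze_profile, doubling_time
from .profiles import (
    BinnedProfile,
    bin_reads,
    cross_sample_correct,
    mask_bins,
    normalize,
    read_bin_counts,
    write_bedgraph,
    write_corrected,
)
from .simulate import SimConfig, SpeedProfile, make_bias_track, simulate_sample

logger = logging.getLogger("replifork")

REPORT_SCHEMA_VERSION = 1

DEFAULTS = {
    "bin_size": 1000,
    "correction_window": 30,
    "mapq_min": 20,
    "mask_low_quantile": 0.001,
    "mask_high_quantile": 0.999,
    "peak_window": 20000,
    "seed": 1,
    "plots": False,
}


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg


def strain_from_config(block: Optional[dict]) -> StrainConfig:
    block = dict(block or {})
    preset = block.pop("preset", None)
    if preset == "mg1655":
        return StrainConfig.mg1655(**block)
    if preset in ("mg1655_oriCX", "oriCX"):
        return StrainConfig.mg1655_oriCX(**block)
    if preset is not None:
        raise ConfigurationError(f"unknown strain preset {preset!r}")
    if not block:
        raise ConfigurationError("strain block is empty")
    return StrainConfig(**block)


def speeds_from_config(block) -> SpeedProfile:
    """Speed block in kbp/s: either {constant: v} or {v4:, v2:, v1:}."""
    if block is None:
        return SpeedProfile.constant(1000.0)
    if isinstance(block, (int, float)):
        return SpeedProfile.constant(float(block) * 1000.0)
    if "constant" in block:
        return SpeedProfile.constant(float(block["constant"]) * 1000.0)
    try:
        return SpeedProfile.from_kbps(block["v4"], block["v2"], block["v1"])
    except KeyError as exc:
        raise ConfigurationError(f"speed block missing {exc}") from None


def _tau_for_sample(sample: dict) -> float:
    """Doubling time in seconds from the sample block (tau / tau_minutes /
    od_series CSV with columns time_min, od)."""
    if "tau" in sample:
        return float(sample["tau"])
    if "tau_minutes" in sample:
        return float(sample["tau_minutes"]) * 60.0
    if "od_series" in sample:
        df = pd.read_csv(sample["od_series"])
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        if "time_min" not in cols or "od" not in cols:
            raise ConfigurationError(
                f"{sample['od_series']}: need columns time_min, od"
            )
        tau_min, r2 = doubling_time(df["time_min"].values, df["od"].values)
        logger.info("sample %s: tau = %.2f min from OD regression (R^2 = %.4f)",
                    sample.get("id"), tau_min, r2)
        return tau_min * 60.0
    raise ConfigurationError(
        f"sample {sample.get('id')!r} has no tau, tau_minutes or od_series"
    )


def _load_samples(cfg: dict, strain: StrainConfig, bin_size: int,
                  mapq_min: int, seed: int) -> list[tuple[BinnedProfile, float]]:
    """Binned profile and doubling time (s) for every sample in the config."""
    out: list[tuple[BinnedProfile, float]] = []
    if "samples" in cfg:
        for sample in cfg["samples"]:
            sid = sample.get("id") or sample.get("counts") or sample.get("alignment")
            tau = _tau_for_sample(sample)
            if "counts" in sample:
                prof = read_bin_counts(sample["counts"], sample_id=sid,
                                       genome_length=strain.genome_length)
                if prof.bin_size != bin_size:
                    raise ConfigurationError(
                        f"{sample['counts']}: bin size {prof.bin_size} != "
                        f"configured {bin_size}"
                    )
            elif "alignment" in sample:
                prof = bin_reads(sample["alignment"], strain.genome_length,
                                 bin_size, mapq_min, sample_id=sid)
            else:
                raise ConfigurationError(
                    f"sample {sid!r} needs a counts or alignment path"
                )
            out.append((prof, tau))
    elif "simulate" in cfg:
        sim_cfg = dict(cfg["simulate"])
        n_samples = int(sim_cfg.pop("n_samples", 1))
        shared_bias = bool(sim_cfg.pop("shared_bias", True))
        speeds = speeds_from_config(sim_cfg.pop("speeds", None))
        sim = SimConfig(strain=strain, speeds=speeds, bin_size=bin_size,
                        seed=seed, **sim_cfg)
        rng = np.random.default_rng(seed)
        bias = None
        if shared_bias and sim.bias_log2_sigma > 0:
            from .profiles import n_bins
            bias = make_bias_track(n_bins(strain.genome_length, bin_size),
                                   sim.bias_log2_sigma,
                                   int(rng.integers(2**31 - 1)))
        for i in range(n_samples):
            sim_i = replace(sim, seed=int(rng.integers(2**31 - 1)))
            prof, _ = simulate_sample(sim_i, sample_id=f"sim{i + 1}",
                                      bias_track=bias)
            out.append((prof, sim.tau))
    else:
        raise ConfigurationError("config needs a 'samples' list or 'simulate' block")
    if not out:
        raise ConfigurationError("no samples to analyse")
    return out


def run_pipeline(cfg: dict, output_dir=None) -> dict:
    """Execute bin -> mask -> normalize -> cross-sample correct -> fit ->
    metrics and write the report bundle.  Returns the report mapping."""
    params = {**DEFAULTS, **{k: v for k, v in cfg.items()
                             if k in DEFAULTS}}
    outdir = Path(output_dir or cfg.get("output_dir", "replifork_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "configuration"
    try:
        strain = strain_from_config(cfg.get("strain"))
        segset = build_segments(strain, params["bin_size"],
                                cfg.get("segment_mode", "auto"))
        logger.info("segmentation (%s): %s", segset.strain_mode,
                    {s.name: (s.start, s.end) for s in segset})

        stage = "input"
        samples = _load_samples(cfg, strain, params["bin_size"],
                                params["mapq_min"], params["seed"])

        stage = "mask/normalize"
        normalized = []
        for prof, tau in samples:
            masked = mask_bins(prof, params["mask_low_quantile"],
                               params["mask_high_quantile"])
            logger.info("sample %s: %d/%d bins retained", prof.sample_id,
                        masked.n_retained, len(masked.counts))
            normalized.append((normalize(masked), tau))

        stage = "cross-sample correction"
        corrected, correction = cross_sample_correct(
            [p for p, _ in normalized], params["correction_window"]
        )

        stage = "fit/metrics"
        results = []
        for prof, (_, tau) in zip(corrected, normalized):
            results.append(analyze_profile(prof, segset, tau, strain,
                                           params["peak_window"]))
    except RepliforkError as exc:
        (outdir / "INCOMPLETE").write_text(f"failed at stage {stage}: {exc}\n")
        raise

    stage = "output"
    chrom = strain.name
    segset.to_bed(outdir / "segments.bed", chrom)
    write_bedgraph(correction, outdir / "correction.bedgraph",
                   strain.genome_length, params["bin_size"], chrom)
    for prof in corrected:
        write_corrected(prof, outdir / f"{prof.sample_id}.corrected.tsv", chrom)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "parameters": {
            **params,
            "segment_mode": segset.strain_mode,
            "genome_length": strain.genome_length,
            "strain": {
                "oriC_pos": strain.oriC_pos,
                "oriX_pos": strain.oriX_pos,
                "terA_pos": strain.terA_pos,
                "terC_pos": strain.terC_pos,
                "ter_extension": strain.ter_extension,
            },
            "one_origin_op_od_convention":
                "identical genomic boundaries as the two-origin segmentation",
        },
        "segments": {
            s.name: {"start": s.start, "end": s.end, "length": s.length,
                     "active_fork_count": s.active_fork_count}
            for s in segset
        },
        "samples": [r.to_dict() for r in results],
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    tsv_rows = []
    for r in results:
        for name, v in r.per_segment_v.items():
            tsv_rows.append({"sample_id": r.sample_id, "segment": name,
                             "v_kbps": round(v, 6),
                             "C_local_s": round(r.per_segment_C.get(name, np.nan), 3)})
    pd.DataFrame(tsv_rows).to_csv(outdir / "per_segment_rfs.tsv", sep="\t",
                                  index=False)

    if params.get("plots"):
        from .plotting import plot_profiles

        plot_profiles(corrected, [r.fit for r in results], segset,
                      outdir / "profiles.svg")
    logger.info("report written to %s", outdir / "report.json")
    return report
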