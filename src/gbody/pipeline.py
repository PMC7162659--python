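"""End-to-end demonstration runs: configuration, seeding, reporting.

One global seed determines every stochastic choice: each stage derives its
own seed as ``crc32("<global_seed>:<stage>") & 0x7FFFFFFF``, so stages are
independent yet the whole run is reproducible bit for bit.  Percentages
are held as fractions internally and formatted as percent only at I/O.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gbody import enrichment, fitness, frap, parclip, puncta, smfish
from gbody import simulate as sim
from gbody.io import write_json

__all__ = ["RunConfig", "stage_seed", "run_demo"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed fan-out (CRC-32 of ``"<seed>:<stage>"``)."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Per-stage parameter blocks with defaults; round-trips through JSON."""

    seed: int = 0
    parclip: dict = field(
        default_factory=lambda: {
            "n_genes": 40,
            "chrom_length": 80_000,
            "n_signal_sites": 8,
            "n_noise_sites": 12,
            "total_reads": 20_000,
            "read_length": 30,
            "threshold_n_iter": 500,
            "threshold_frac": 0.20,
            "mixture_n_noise": 300,
            "mixture_n_signal": 100,
        }
    )
    ripseq: dict = field(
        default_factory=lambda: {
            "n_genes": 300,
            "n_enriched": 20,
            "fold": 4.0,
            "n_reps": 3,
            "dispersion": 0.05,
            "lib_size": 300_000,
            "fold_thresh": 2.0,
            "alpha": 0.05,
        }
    )
    puncta: dict = field(
        default_factory=lambda: {
            "pixel_size": 0.13,
            "side_um": 4.9,
            "n_puncta": 5,
            "noise_sd": 5.0,
        }
    )
    smfish: dict = field(
        default_factory=lambda: {"pixel_size": 0.13, "n_spots": 60}
    )
    frap: dict = field(
        default_factory=lambda: {
            "A_true": 0.30,
            "half_time_min": 10.0,
            "noise_sd": 0.02,
            "t_max": 40.0,
        }
    )
    competition: dict = field(
        default_factory=lambda: {
            "f_true": 0.65,
            "pct_gb_plus": 90.0,
            "pct_gb_minus": 10.0,
            "n_cells": 10_000,
        }
    )

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        return cls(**data)


def _demo_parclip(cfg: dict, seed: int) -> dict:
    annot = sim.make_annotation(
        cfg["n_genes"], chrom_length=cfg["chrom_length"], seed=seed
    )
    truth = sim.make_site_truth(
        annot,
        n_signal=cfg["n_signal_sites"],
        n_noise=cfg["n_noise_sites"],
        seed=seed + 1,
        dataset_id="demoA",
    )
    reads = sim.simulate_parclip_reads(
        annot,
        truth,
        total_reads=cfg["total_reads"],
        read_length=cfg["read_length"],
        seed=seed + 2,
    )
    sites = parclip.assemble_binding_sites(reads, total_mapped=cfg["total_reads"])

    if cfg["threshold_n_iter"] < 100:
        warnings.warn(
            "threshold_n_iter < 100: the mean K-S curve may be unstable",
            stacklevel=2,
        )
    rpm, labels = sim.simulate_site_rpm_mixture(
        n_noise=cfg["mixture_n_noise"],
        n_signal=cfg["mixture_n_signal"],
        seed=seed + 3,
    )
    curve = parclip.empirical_rpm_threshold(
        rpm,
        n_iter=cfg["threshold_n_iter"],
        frac=cfg["threshold_frac"],
        seed=seed + 4,
    )
    kept = rpm >= curve.chosen
    noise_excluded = float((~kept & ~labels).sum() / max((~labels).sum(), 1))
    signal_kept = float((kept & labels).sum() / max(labels.sum(), 1))

    # a second dataset over the same annotation for overlap/target stages
    truth_b = sim.make_site_truth(
        annot,
        n_signal=cfg["n_signal_sites"],
        n_noise=cfg["n_noise_sites"],
        seed=seed + 5,
        dataset_id="demoB",
    )
    reads_b = sim.simulate_parclip_reads(
        annot,
        truth_b,
        total_reads=cfg["total_reads"],
        read_length=cfg["read_length"],
        seed=seed + 6,
    )
    sites_b = parclip.assemble_binding_sites(reads_b, total_mapped=cfg["total_reads"])
    overlap = parclip.classify_site_overlap({"demoA": sites, "demoB": sites_b})
    _, fractions = parclip.annotate_sites(sites, annot)
    gene_sets, venn = parclip.target_gene_sets(
        {"demoA": sites, "demoB": sites_b}, annot
    )
    return {
        "n_sites": len(sites),
        "chosen_rpm_threshold": curve.chosen,
        "threshold_stabilized": curve.stabilized,
        "noise_fraction_excluded": noise_excluded,
        "signal_fraction_kept": signal_kept,
        "region_fractions": fractions,
        "overlap_class_counts": {
            ds: {c: lab.count(c) for c in ("identical", "overlapping", "unique")}
            for ds, lab in overlap.items()
        },
        "venn_counts": venn,
        "n_target_genes": {ds: len(s) for ds, s in gene_sets.items()},
    }


def _demo_ripseq(cfg: dict, seed: int) -> dict:
    annot = sim.make_annotation(cfg["n_genes"], chrom_length=400_000, seed=seed)
    gene_ids = [g.gene_id for g in annot.genes]
    enriched = set(gene_ids[: cfg["n_enriched"]])
    tables = sim.simulate_ripseq_counts(
        annot,
        enriched,
        fold=cfg["fold"],
        n_reps=cfg["n_reps"],
        dispersion=cfg["dispersion"],
        lib_size=cfg["lib_size"],
        seed=seed + 1,
    )
    rpm = {arm: enrichment.normalize_rpm(df) for arm, df in tables.items()}
    vs_ft = enrichment.enrichment_test(rpm["ip"], rpm["ft"])
    vs_total = enrichment.enrichment_test(rpm["ip"], rpm["total"])
    hc, counts = enrichment.high_confidence_set(
        vs_ft, vs_total, cfg["fold_thresh"], cfg["alpha"]
    )
    sens = len(hc & enriched) / len(enriched)
    chisq = enrichment.overlap_chisq(hc, set(gene_ids), enriched)
    cq = enrichment.CqRecord("demo_probe", cq_eluate=25.0, cq_flow_through=24.0)
    return {
        "screen_counts": counts,
        "high_confidence_sensitivity": sens,
        "overlap_chisq": chisq,
        "qpcr_percent_input_demo": enrichment.qpcr_percent_input(cq),
    }


def _demo_puncta(cfg: dict, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    cells = [
        sim.CellDescriptor(center=(32, 32), radius=20, baseline=100.0, label=1),
        sim.CellDescriptor(center=(32, 96), radius=20, baseline=100.0, label=2),
        sim.CellDescriptor(center=(96, 64), radius=20, baseline=100.0, label=3),
    ]
    puncta_truth = []
    for k in range(cfg["n_puncta"]):
        cell = cells[k % len(cells)]
        puncta_truth.append(
            sim.PunctumTruth(
                A=1000.0 + 200.0 * k,
                x0=cell.center[1] + float(rng.uniform(-5, 5)),
                y0=cell.center[0] + float(rng.uniform(-5, 5)),
                sigma_x=float(rng.uniform(2.0, 4.0)),
                sigma_y=float(rng.uniform(2.0, 4.0)),
                theta=float(rng.uniform(0, np.pi)),
                b=100.0,
                z0=2.0,
            )
        )
    stack = sim.simulate_image_stack(
        cells,
        puncta_truth,
        shape=(5, 128, 128),
        noise_model=(cfg["noise_sd"], False),
        pixel_size=cfg["pixel_size"],
        seed=seed + 1,
    )
    proj = stack.channels["gfp"].max(axis=0)
    corrected, bg = puncta.subtract_background(
        proj, [(0, 8, 0, 8), (0, 8, 120, 128), (120, 128, 0, 8)]
    )
    peaks = puncta.detect_maxima(corrected, prominence=400.0, min_distance=5)
    fits = []
    for peak in peaks:
        patch, _, _ = puncta.extract_patch(
            corrected, tuple(peak), cfg["side_um"], cfg["pixel_size"]
        )
        fits.append(puncta.fit_gaussian2d(patch, pixel_size=cfg["pixel_size"]))
    labels = stack.cell_label_image(proj.shape)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # demo uses < 100 cells
        _, fractions, _ = puncta.classify_cells(labels, peaks)
    sigmas_um = sorted(
        round(f.sigma_x_um, 6) for f in fits if f.converged and f.sigma_x_um
    )
    return {
        "background_estimate": bg,
        "n_detected": int(len(peaks)),
        "n_planted": cfg["n_puncta"],
        "cell_fractions": fractions,
        "fitted_sigma_x_um": sigmas_um,
    }


def _demo_smfish(cfg: dict, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    px = cfg["pixel_size"]
    cells = [sim.CellDescriptor(center=(64, 64), radius=50, baseline=50.0)]
    gbody = sim.PunctumTruth(
        A=2000.0, x0=64.0, y0=64.0, sigma_x=3.0, sigma_y=3.0, b=50.0, z0=2.0
    )
    n = cfg["n_spots"]
    # target spots cluster near the granule; control spots are uniform
    target_xy = 64.0 + rng.normal(0, 2.5, size=(n, 2))
    control_xy = 64.0 + rng.uniform(-40, 40, size=(n, 2))
    spots = [(float(x), float(y), int(rng.integers(1, 4))) for x, y in target_xy]
    stack = sim.simulate_image_stack(
        cells, [gbody], spots=spots, shape=(5, 128, 128), pixel_size=px,
        noise_model=(2.0, False), seed=seed + 1,
    )
    outline = stack.cell_label_image((128, 128)) > 0
    seg = smfish.segment_gbody(stack.channels["gfp"], outline)
    near = smfish.select_spots_near_plane(
        np.array([(y, x, z) for x, y, z in spots]), seg.slice_index
    )
    prof_t = smfish.distance_profile(seg.center, near[:, :2], px)
    prof_c = smfish.distance_profile(
        seg.center, np.column_stack([control_xy[:, 1], control_xy[:, 0]]), px
    )
    grid = np.linspace(0.25, 5.0, 20)
    fc = smfish.cdf_fold_change(prof_t, prof_c, grid)
    return {
        "gbody_found": seg.found,
        "gbody_center": [round(v, 3) for v in seg.center],
        "in_focus_slice": seg.slice_index,
        "pct_within_one_pixel_target": prof_t.percent_within_one_pixel,
        "pct_within_one_pixel_control": prof_c.percent_within_one_pixel,
        "fold_change_at_1um": float(
            fc[int(np.argmin(np.abs(grid - 1.0)))]
        ),
    }


def _demo_frap(cfg: dict, seed: int) -> dict:
    tau = np.log(2.0) / cfg["half_time_min"]
    trace = sim.simulate_frap_trace(
        A_true=cfg["A_true"],
        tau_true=tau,
        bleach_depth=0.8,
        acquisition_bleach_rate=0.01,
        noise_sd=cfg["noise_sd"],
        seed=seed,
    )
    corrected = frap.correct_trace(trace)
    kept = frap.filter_bleach_depth(corrected)
    fit = frap.fit_recovery(corrected, t_max=cfg["t_max"])
    return {
        "trace_kept": kept,
        "A_true": cfg["A_true"],
        "A_fit": fit.A,
        "half_time_true_min": cfg["half_time_min"],
        "half_time_fit_min": fit.half_time,
        "converged": fit.converged,
    }


def _demo_competition(cfg: dict, seed: int) -> dict:
    obs = sim.simulate_competition(
        f_true=cfg["f_true"],
        pct_gb_plus=cfg["pct_gb_plus"],
        pct_gb_minus=cfg["pct_gb_minus"],
        n_cells=cfg["n_cells"],
        seed=seed,
    )
    est = fitness.fraction_gb_plus(obs, seed=seed + 1)
    return {
        "f_true": cfg["f_true"],
        "f_estimate": est.f_gb_plus,
        "ci": [est.ci_low, est.ci_high],
        "generations_od_0.05_to_4.2": fitness.generations(0.05, 4.2),
    }


_STAGES = {
    "parclip": _demo_parclip,
    "ripseq": _demo_ripseq,
    "puncta": _demo_puncta,
    "smfish": _demo_smfish,
    "frap": _demo_frap,
    "competition": _demo_competition,
}


def run_demo(config: RunConfig | None = None, outdir=None) -> dict:
    """Generate synthetic data for all six analyses, run every stage, and
    return (and optionally write) a single report of parameter-recovery
    results.  Byte-identical across repeat runs at a fixed seed.
    """
    config = config or RunConfig()
    report: dict = {"seed": config.seed, "stages": {}}
    for name, fn in _STAGES.items():
        cfg = getattr(config, name if name != "competition" else "competition")
        try:
            report["stages"][name] = fn(cfg, stage_seed(config.seed, name))
        except Exception as exc:  # preserve partial outputs, name the stage
            if outdir is not None:
                Path(outdir).mkdir(parents=True, exist_ok=True)
                write_json(report, Path(outdir) / "report_partial.json")
            raise RuntimeError(f"demo stage {name!r} failed: {exc}") from exc
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_json(report, outdir / "report.json")
        config.to_json(outdir / "config.json")
    return report
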