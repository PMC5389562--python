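"""End-to-end orchestration: simulate/load -> detect -> register -> colocalize
-> count steps -> occupancy statistics.

One :class:`RunConfig` drives a full run; every stage parameter is
echoed into the :class:`Report` for provenance, and with a synthetic
source the report also carries a truth-vs-inferred comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from smstoich import io as sio
from smstoich.chromalign import Affine2D, colocalize, fit_transform
from smstoich.simkit import SimConfig, simulate_field
from smstoich.spotfind import DetectionParams, detect_spots, detection_image, \
    extract_trace
from smstoich.stepfit import ND, StepFitParams, classify_trace, fit_steps
from smstoich.stoichfit import (
    GofResult,
    LabelingParams,
    OccupancyFit,
    StepHistogram,
    binomial_error,
    fit_occupancy_mixture,
    single_site_distribution,
    single_site_gof,
)

__all__ = ["RunConfig", "Report", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be set: a synthetic ``sim`` config,
    paths to per-channel TIFF ``stacks`` ({"rna": ..., "protein": ...}),
    or a pre-extracted ``traces`` table.
    """

    sim: SimConfig | None = None
    stacks: dict[str, str] | None = None
    traces: str | None = None
    labeling: LabelingParams | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    stepfit: StepFitParams = field(default_factory=StepFitParams)
    match_radius: float = 2.0
    registration_radius: float = 4.0
    roi_radius: float = 3.0
    transform: Affine2D | None = None  # None: estimate from spot pairs
    label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        sources = [s is not None for s in (self.sim, self.stacks, self.traces)]
        if sum(sources) != 1:
            raise ValueError("exactly one input source must be set")


@dataclass
class Report:
    """Everything one run produced, JSON-serializable."""

    label: str
    n_rna: int
    n_protein_spots: int
    n_colocalized: int
    colocalized_fraction: float
    colocalized_se: float
    step_counts: dict[int, int]
    nd_count: int
    gof_k1: GofResult | None
    gof_k2: GofResult | None
    occupancy: OccupancyFit | None
    transform: Affine2D | None
    truth_comparison: dict | None
    config_hash: str
    seed: int
    params: dict

    def to_dict(self) -> dict:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            return o

        return enc(dataclasses.asdict(self))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Report":
        d = json.loads(text)
        d["step_counts"] = {int(k): int(v) for k, v in d["step_counts"].items()}
        if d.get("gof_k1"):
            d["gof_k1"] = GofResult(**{**d["gof_k1"],
                                       "classes": [tuple(c) for c in d["gof_k1"]["classes"]]})
        if d.get("gof_k2"):
            d["gof_k2"] = GofResult(**{**d["gof_k2"],
                                       "classes": [tuple(c) for c in d["gof_k2"]["classes"]]})
        if d.get("occupancy"):
            d["occupancy"] = OccupancyFit(pi=tuple(d["occupancy"]["pi"]),
                                          n_accessible=d["occupancy"]["n_accessible"],
                                          chisq=d["occupancy"]["chisq"])
        if d.get("transform"):
            t = d["transform"]
            d["transform"] = Affine2D(tuple(map(tuple, t["linear"])),
                                      tuple(t["offset"]), t.get("rms_residual", 0.0))
        return cls(**d)


def _config_hash(config: RunConfig) -> str:
    text = repr(config)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _estimate_transform(rna_xy, prot_xy, radius: float) -> Affine2D:
    """Bootstrap registration from bright-spot pairs via a coarse match."""
    coarse = colocalize(rna_xy, prot_xy, None, radius=radius)
    if len(coarse.pairs) < 3:
        return Affine2D.identity()
    ref = np.array([rna_xy[i] for i, _, _ in coarse.pairs])
    mov = np.array([prot_xy[j] for _, j, _ in coarse.pairs])
    try:
        return fit_transform(ref, mov)
    except ValueError:
        return Affine2D.identity()


def run_pipeline(config: RunConfig) -> Report:
    """Execute all stages in order and assemble the report."""
    rng = np.random.default_rng(config.seed)
    labeling = config.labeling
    truth = None
    traces: list[np.ndarray]
    transform = config.transform

    if config.traces is not None:
        traces, _ = sio.read_traces(config.traces)
        n_rna = len(traces)
        n_protein_spots = len(traces)
        n_coloc_known = None
    else:
        if config.sim is not None:
            stacks, truth = simulate_field(config.sim, rng)
            if labeling is None:
                labeling = config.sim.labeling
            det = dataclasses.replace(
                config.detection,
                crop_origin=config.sim.crop_origin,
                crop_size=config.sim.crop_size,
            )
        else:
            import tifffile

            stacks = {k: tifffile.imread(v) for k, v in config.stacks.items()}
            det = config.detection

        rna_img = detection_image(stacks["rna"])
        prot_img = detection_image(stacks["protein"])
        rna_spots = detect_spots(rna_img, det, channel="rna")
        prot_spots = detect_spots(prot_img, det, channel="protein")
        rna_xy = np.array([[s.x, s.y] for s in rna_spots]).reshape(-1, 2)
        prot_xy = np.array([[s.x, s.y] for s in prot_spots]).reshape(-1, 2)
        n_rna = len(rna_spots)
        n_protein_spots = len(prot_spots)

        # `transform` maps protein-channel coordinates into the RNA frame
        if transform is None and n_rna and n_protein_spots:
            transform = _estimate_transform(rna_xy, prot_xy,
                                            config.registration_radius)
        match = colocalize(rna_xy, prot_xy, transform, radius=config.match_radius)
        n_coloc_known = len(match.pairs)
        traces = []
        for _, j, _ in match.pairs:
            tr, clipped = extract_trace(
                stacks["protein"], prot_xy[j, 0], prot_xy[j, 1],
                roi_radius=config.roi_radius,
            )
            if not clipped:
                traces.append(tr)

    # step counting
    counts: dict[int, int] = {}
    nd = 0
    for tr in traces:
        try:
            fit = fit_steps(tr, config.stepfit)
            verdict = classify_trace(fit, config.stepfit).verdict
        except ValueError:
            verdict = ND
        if verdict == ND or verdict == 0:
            nd += 1
        else:
            counts[verdict] = counts.get(verdict, 0) + 1

    n_coloc = n_coloc_known if n_coloc_known is not None else sum(counts.values()) + nd
    hist = StepHistogram(counts=counts, nd_count=n_coloc - sum(counts.values()),
                         total_rna=max(n_rna, n_coloc))
    frac = hist.colocalized_fraction if n_rna else 0.0
    se = binomial_error(hist.total_colocalized, max(n_rna, 1)) if n_rna else 0.0

    gof1 = gof2 = occ = None
    if labeling is not None and sum(counts.values()) > 0:
        for sites, slot in ((1, "gof_k1"), (2, "gof_k2")):
            try:
                res = single_site_gof(hist, labeling, sites=sites)
            except ValueError:
                res = None
            if sites == 1:
                gof1 = res
            else:
                gof2 = res
        try:
            single = single_site_distribution(labeling.dimer_1step,
                                              labeling.dimer_2step)
            m_vis = hist.total_scored
            n_hi = max(n_rna, m_vis)
            step = max(1, (n_hi - m_vis) // 100)
            occ = fit_occupancy_mixture(hist, single, labeling.f_labeled,
                                        range(m_vis, n_hi + 1, step))
        except ValueError:
            occ = None

    truth_cmp = None
    if truth is not None:
        visible = truth.table["n_fluor_protein"].to_numpy()
        true_counts = {int(k): int(v) for k, v in
                       zip(*np.unique(visible[visible > 0], return_counts=True))}
        truth_cmp = {
            "true_visible_counts": true_counts,
            "true_visible_fraction": float(np.mean(visible > 0))
            if len(visible) else 0.0,
            "true_n_rna": int(len(visible)),
            "inferred_counts": dict(counts),
        }

    params = {
        "detection": dataclasses.asdict(config.detection),
        "stepfit": dataclasses.asdict(config.stepfit),
        "match_radius": config.match_radius,
        "roi_radius": config.roi_radius,
        "labeling": dataclasses.asdict(labeling) if labeling else None,
    }
    return Report(
        label=config.label,
        n_rna=n_rna,
        n_protein_spots=n_protein_spots,
        n_colocalized=n_coloc,
        colocalized_fraction=frac,
        colocalized_se=se,
        step_counts=counts,
        nd_count=hist.nd_count,
        gof_k1=gof1,
        gof_k2=gof2,
        occupancy=occ,
        transform=transform,
        truth_comparison=truth_cmp,
        config_hash=_config_hash(config),
        seed=config.seed,
        params=params,
    )


def write_report(report: Report, out_dir: str | Path) -> None:
    """Write the JSON report, a step histogram table and a text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())

    import pandas as pd

    rows = [{"steps": k, "count": v} for k, v in sorted(report.step_counts.items())]
    rows.append({"steps": "n.d.", "count": report.nd_count})
    pd.DataFrame(rows, columns=["steps", "count"]).to_csv(
        out / "step_histogram.tsv", sep="\t", index=False
    )

    lines = [
        f"run: {report.label or '(unlabeled)'}",
        f"RNA spots examined: {report.n_rna}",
        f"colocalized: {report.n_colocalized} "
        f"({100 * report.colocalized_fraction:.1f}% "
        f"+/- {100 * report.colocalized_se:.1f}%)",
        "step counts: "
        + ", ".join(f"{k}: {v}" for k, v in sorted(report.step_counts.items()))
        + f", n.d.: {report.nd_count}",
    ]
    if report.gof_k1:
        lines.append(f"single-occupancy chi-square: {report.gof_k1.statistic:.3f} "
                     f"(df {report.gof_k1.df}, P = {report.gof_k1.pvalue:.3g})")
    if report.gof_k2:
        lines.append(f"double-occupancy chi-square: {report.gof_k2.statistic:.3f} "
                     f"(df {report.gof_k2.df}, P = {report.gof_k2.pvalue:.3g})")
    if report.occupancy:
        pi = report.occupancy.pi
        lines.append(
            f"occupancy mixture: pi0={pi[0]:.2f} pi1={pi[1]:.2f} pi2={pi[2]:.2f} "
            f"(N={report.occupancy.n_accessible}, "
            f"chi2={report.occupancy.chisq:.2f})"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
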