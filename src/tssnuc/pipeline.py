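"""End-to-end orchestration: classify -> profile -> scan, with a manifest.

Every stage is a pure function of (inputs, config); re-running on the same
inputs reproduces byte-identical outputs, recorded as SHA-256 hashes in
``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .classify import (
    BOE_CLASSES,
    CHROMATIN_CLASSES,
    RPKM_CLASSES,
    ClassificationConfig,
    ClassificationResult,
    build_classification,
)
from .correlation import scan_by_class
from .io import (
    read_bed_domains,
    read_bed_sites_frame,
    read_gene_table,
    write_table,
)
from .model import RESISTANT, SENSITIVE, STATE_MAPPINGS
from .profiles import average_profile, build_count_matrix, find_peaks

logger = logging.getLogger(__name__)

#: (label, search interval, number of peaks) used for the peak report
PEAK_REPORT_INTERVALS = (
    ("downstream", (1, 199), 1),  # Nuc+1
    ("upstream", (-299, -1), 2),  # Nuc-1, Nuc-2
)


@dataclass
class PipelineParams:
    """Flags shared across the pipeline stages."""

    states: str = "4hmm"
    window: tuple[int, int] = (-300, 200)
    smooth_window: int = 3
    boe_threshold: float = 3.0
    gap_policy: str = "modest"
    alpha: float = 0.05
    bonferroni_m: int | None = None  # default: number of scanned offsets
    tie_corrected: bool = False
    make_plots: bool = False

    def classification_config(self) -> ClassificationConfig:
        return ClassificationConfig(
            boe_rpkm_threshold=self.boe_threshold,
            window=self.window,
            gap_policy=self.gap_policy,
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    genes_path: str,
    domains_path: str,
    resistant_path: str,
    sensitive_path: str,
    outdir: str,
    params: PipelineParams | None = None,
) -> dict:
    """Run classification, metagene profiling, peak localisation and the
    correlation scans; write all tables plus a run manifest to ``outdir``.

    Emits per stratification axis (BoE classes and RPKM classes) the
    2 chromatin classes x 3 strata x 2 sensitivities profile grid, the
    matching Kendall correlation profiles with Bonferroni masks, and a
    peak report for the class-level profiles.
    """
    params = params or PipelineParams()
    if params.states not in STATE_MAPPINGS:
        raise ValueError(f"states must be one of {sorted(STATE_MAPPINGS)}")
    mapping = STATE_MAPPINGS[params.states]
    os.makedirs(outdir, exist_ok=True)

    genes = read_gene_table(genes_path)
    domains = read_bed_domains(domains_path, mapping.alphabet)
    site_frames = {
        RESISTANT: read_bed_sites_frame(resistant_path, RESISTANT),
        SENSITIVE: read_bed_sites_frame(sensitive_path, SENSITIVE),
    }
    logger.info(
        "loaded %d genes, %d domains, %d resistant / %d sensitive sites",
        len(genes),
        len(domains),
        len(site_frames[RESISTANT]),
        len(site_frames[SENSITIVE]),
    )

    # --- classification -------------------------------------------------
    cls_config = params.classification_config()
    result: ClassificationResult = build_classification(genes, domains, mapping, cls_config)
    table = result.table
    outputs: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(outdir, name)
        write_table(df, path)
        outputs[name] = _sha256(path)

    emit("classification.tsv", table)
    ct_rows = []
    for cc in CHROMATIN_CLASSES:
        ct = result.crosstabs[cc]
        for r in RPKM_CLASSES:
            for b in BOE_CLASSES:
                ct_rows.append(
                    {"chromatin_class": cc, "rpkm_class": r, "boe_class": b, "n_genes": int(ct.loc[r, b])}
                )
    emit("crosstab.tsv", pd.DataFrame(ct_rows))
    for cc in CHROMATIN_CLASSES:
        logger.info(
            "%s: %d genes (expressed fraction %.3f)",
            cc,
            int(result.summary.get(f"n_{cc.lower()}", 0)),
            result.summary.get(f"frac_{cc.lower()}_expressed", float("nan")),
        )

    # --- count matrices (full gene set, one per sensitivity) -----------
    matrices = {
        sens: build_count_matrix(genes, frame, window=params.window, sensitivity=sens)
        for sens, frame in site_frames.items()
    }

    # --- metagene profiles and peak report ------------------------------
    profile_rows = {"boe_class": [], "rpkm_class": []}
    peak_rows = []
    class_profiles = {}
    for cc in CHROMATIN_CLASSES:
        ids_cc = table.loc[table["chromatin_class"] == cc, "gene_id"].tolist()
        for sens, matrix in matrices.items():
            if not ids_cc:
                continue
            prof = average_profile(matrix.subset(ids_cc), params.smooth_window)
            class_profiles[(cc, sens)] = prof
            for label, interval, k in PEAK_REPORT_INTERVALS:
                for rank, off in enumerate(find_peaks(prof, interval, k), start=1):
                    height = float(prof.smoothed[list(prof.offsets).index(off)])
                    peak_rows.append(
                        {
                            "chromatin_class": cc,
                            "sensitivity": sens,
                            "region": label,
                            "rank": rank,
                            "offset": off,
                            "smoothed_height": height,
                        }
                    )
        for stratifier, strata in (("boe_class", BOE_CLASSES), ("rpkm_class", RPKM_CLASSES)):
            for stratum in strata:
                ids = table.loc[
                    (table["chromatin_class"] == cc) & (table[stratifier] == stratum),
                    "gene_id",
                ].tolist()
                if not ids:
                    logger.warning("empty stratum %s/%s", cc, stratum)
                    continue
                for sens, matrix in matrices.items():
                    prof = average_profile(matrix.subset(ids), params.smooth_window)
                    profile_rows[stratifier].append(
                        pd.DataFrame(
                            {
                                "chromatin_class": cc,
                                "stratum": stratum,
                                "sensitivity": sens,
                                "offset": prof.offsets,
                                "mean_count": prof.mean_count,
                                "smoothed": prof.smoothed,
                                "n_genes": prof.n_genes,
                            }
                        )
                    )
    emit("profiles_by_boe_class.tsv", pd.concat(profile_rows["boe_class"], ignore_index=True))
    emit("profiles_by_rpkm_class.tsv", pd.concat(profile_rows["rpkm_class"], ignore_index=True))
    emit("peaks.tsv", pd.DataFrame(peak_rows))

    # --- correlation scans ----------------------------------------------
    scan_outputs = {}
    for covariate, stratifier in (("RPKM", "boe_class"), ("BoE", "rpkm_class")):
        profiles = scan_by_class(
            table,
            matrices,
            covariate=covariate,
            stratifier=stratifier,
            alpha=params.alpha,
            m=params.bonferroni_m,
            tie_corrected=params.tie_corrected,
        )
        frames = []
        for p in profiles:
            df = p.to_frame()
            for key in ("chromatin_class", "stratum", "sensitivity"):
                df.insert(0, key, p.labels[key])
            df["n_genes"] = p.n
            frames.append(df)
        name = f"correlation_{covariate.lower()}.tsv"
        emit(name, pd.concat(frames, ignore_index=True))
        scan_outputs[covariate] = profiles

    if params.make_plots:
        from .plotting import plot_class_profiles, plot_correlation_profiles

        plot_class_profiles(class_profiles, os.path.join(outdir, "profiles.png"))
        plot_correlation_profiles(
            scan_outputs["RPKM"], os.path.join(outdir, "correlation_rpkm.png")
        )
        outputs["profiles.png"] = _sha256(os.path.join(outdir, "profiles.png"))

    manifest = {
        "tool_version": __version__,
        "inputs": {
            "genes": _sha256(genes_path),
            "domains": _sha256(domains_path),
            "resistant": _sha256(resistant_path),
            "sensitive": _sha256(sensitive_path),
        },
        "params": {
            "states": params.states,
            "window": list(params.window),
            "smooth_window": params.smooth_window,
            "boe_threshold": params.boe_threshold,
            "gap_policy": params.gap_policy,
            "alpha": params.alpha,
            "bonferroni_m": params.bonferroni_m,
            "tie_corrected": params.tie_corrected,
        },
        "counts": {
            "genes": len(genes),
            "domains": len(domains),
            "resistant_sites": int(len(site_frames[RESISTANT])),
            "sensitive_sites": int(len(site_frames[SENSITIVE])),
            **{k: v for k, v in result.summary.items()},
        },
        "outputs": outputs,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
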