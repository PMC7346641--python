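"""One-command orchestration of the full HGT-network analysis.

Given a config naming the input files (events, metadata, taxonomy, depth,
annotations) and parameters, runs the stages in dependency order —

    build → fit → entropy/rate → similarity → communities → hec → fusion

— writes every stage's table under the output directory, and serializes a
machine-readable JSON report. Reports are written via write-then-rename so
a failed run never leaves a half-written report. Reruns with the same
config and seed reproduce all deterministic outputs.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from . import communities as communities_mod
from . import entropy_similarity as entsim
from . import event_clusters as hec_mod
from . import fusion as fusion_mod
from . import netbuild
from . import scalefree
from .data_model import (
    read_depth,
    read_events,
    read_gene_annotations,
    read_metadata,
    read_taxonomy,
    write_network,
)
from .errors import ConfigError, HgtNetError

log = logging.getLogger("hgtnet.pipeline")

ALL_STAGES = ("build", "fit", "entropy_rate", "similarity", "communities",
              "hec", "fusion")

_DEFAULTS: dict[str, Any] = {
    "bin_size": 100,
    "seed": 0,
    "resolution": 1.0,
    "min_nodes": 100,
    "hcc_cut": communities_mod.DEFAULT_HCC_CUT,
    "hcc_min_size": communities_mod.DEFAULT_HCC_MIN_SIZE,
    "hec_preset": None,
    "hec_min_samples": 4,
    "hec_min_class_size": 20,
    "hec_cut": hec_mod.DEFAULT_HEC_CUT,
    "network_format": "weighted-edge-list",
    "stages": list(ALL_STAGES),
}


def load_config(path: str | Path) -> dict[str, Any]:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _validate_config(cfg: Mapping[str, Any]) -> dict[str, Any]:
    merged = dict(_DEFAULTS)
    merged.update(cfg)
    stages = merged["stages"]
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s) {unknown}; valid: {list(ALL_STAGES)}")
    for req in ("events", "metadata", "out_dir"):
        if req not in merged:
            raise ConfigError(f"config missing required key {req!r}")
    needs = {
        "entropy_rate": ["depth"],
        "communities": ["taxonomy"],
        "hec": ["taxonomy"],
        "fusion": ["annotations"],
    }
    for stage, keys in needs.items():
        if stage in stages:
            for key in keys:
                if key not in merged:
                    raise ConfigError(
                        f"stage {stage!r} requires config key {key!r}"
                    )
    for key in ("events", "metadata", "taxonomy", "depth", "annotations"):
        if key in merged and not Path(merged[key]).exists():
            raise ConfigError(f"{key} file not found: {merged[key]}")
    return merged


def run_pipeline(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Run the configured stages; returns the report dict (also written as
    ``report.json`` in the output directory)."""
    cfg = _validate_config(
        load_config(config) if isinstance(config, (str, Path)) else config
    )
    stages = cfg["stages"]
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {
        "run": {
            "version": __version__,
            "seed": cfg["seed"],
            "parameters": {k: v for k, v in cfg.items()
                           if k not in ("stages",)},
            "stages": list(stages),
        },
        "samples": {},
    }
    t_all = time.monotonic()
    current = "load"
    try:
        events = read_events(cfg["events"], bin_size=cfg["bin_size"])
        metadata = read_metadata(cfg["metadata"])
        log.info("loaded %d events, %d samples", len(events), len(metadata))

        networks = netbuild.build_networks_by_sample(events)
        for sid in metadata:
            report["samples"].setdefault(sid, {})["network_size"] = (
                networks[sid].number_of_nodes() if sid in networks else 0
            )

        if "build" in stages:
            current = "build"
            t0 = time.monotonic()
            net_dir = out / "networks"
            net_dir.mkdir(exist_ok=True)
            ext = "graphml" if cfg["network_format"] == "graphml" else "edges"
            for sid, net in networks.items():
                write_network(net, net_dir / f"{sid}.{ext}", cfg["network_format"])
            log.info("build: %d networks written (%.1fs)", len(networks),
                     time.monotonic() - t0)

        if "fit" in stages:
            current = "fit"
            t0 = time.monotonic()
            fit_rows = []
            alphas_by_group: dict[str, list[float]] = {}
            for sid, net in networks.items():
                degrees = list(net.degrees().values())
                if len(degrees) < cfg["min_nodes"]:
                    continue
                try:
                    pf = scalefree.fit_power_law(degrees, min_degrees=cfg["min_nodes"])
                    llrs = scalefree.compare_all(degrees, power_fit=pf)
                except HgtNetError as exc:
                    log.warning("fit skipped for %s: %s", sid, exc)
                    continue
                row = {"sample": sid, "alpha": pf.alpha, "xmin": pf.xmin,
                       "ks": pf.ks_distance, "n_tail": pf.n_tail}
                for fam, res in llrs.items():
                    row[f"llr_{fam}"] = res.ratio
                    row[f"p_{fam}"] = res.p_value
                fit_rows.append(row)
                report["samples"][sid]["alpha"] = pf.alpha
                report["samples"][sid]["xmin"] = pf.xmin
                report["samples"][sid]["llr"] = {
                    fam: {"ratio": r.ratio, "p": r.p_value, "winner": r.winner}
                    for fam, r in llrs.items()
                }
                alphas_by_group.setdefault(metadata[sid].group, []).append(pf.alpha)
            _write_tsv(out / "fits.tsv", fit_rows)
            usable = {g: v for g, v in alphas_by_group.items() if len(v) >= 2}
            if len(usable) >= 1:
                report["group_fits"] = [
                    asdict(s) for s in scalefree.summarize_group_fits(usable)
                ]
            fitted = [networks[r["sample"]] for r in fit_rows]
            try:
                trend = scalefree.diameter_lnlnN_trend(fitted)
                report["diameter_trend"] = {
                    "slope": trend.slope, "intercept": trend.intercept,
                    "r": trend.r, "n": len(trend.points),
                }
            except HgtNetError as exc:
                log.warning("diameter trend unavailable: %s", exc)
            log.info("fit: %d networks (%.1fs)", len(fit_rows), time.monotonic() - t0)

        if "entropy_rate" in stages:
            current = "entropy_rate"
            t0 = time.monotonic()
            depth = read_depth(cfg["depth"])
            rows = []
            for sid, net in networks.items():
                h = entsim.von_neumann_entropy(net).H_VN
                report["samples"][sid]["H_VN"] = h
                row = {"sample": sid, "H_VN": h}
                if sid in depth:
                    rate = netbuild.hgt_event_rate(net.total_events(), depth[sid])
                    report["samples"][sid]["event_rate"] = rate.rate
                    row.update(H=rate.H, depth=rate.depth, rate=rate.rate)
                rows.append(row)
            _write_tsv(out / "entropy_rates.tsv", rows)
            log.info("entropy_rate: %d samples (%.1fs)", len(rows),
                     time.monotonic() - t0)

        if "similarity" in stages:
            current = "similarity"
            t0 = time.monotonic()
            scores = entsim.all_pairwise_similarities(networks)
            _write_tsv(out / "similarity.tsv", [
                {"sample_a": s.sample_a, "sample_b": s.sample_b,
                 "metric": s.metric, "value": s.value,
                 "correlation_undefined": s.correlation_undefined}
                for s in scores
            ])
            pairing = {}
            for s in scores:
                ia, ib = metadata[s.sample_a].individual_id, metadata[s.sample_b].individual_id
                fam_a, fam_b = ia.split("_")[0], ib.split("_")[0]
                pairing[(s.sample_a, s.sample_b)] = (
                    "within" if fam_a == fam_b else "between"
                )
            combined = [s for s in scores if s.metric == "combined"]
            try:
                cmp = entsim.within_between_test(combined, pairing)
                report["similarity_test"] = {
                    "t": cmp.t_statistic, "p_two_sided": cmp.p_value,
                    "p_within_greater": cmp.p_one_sided,
                    "n_within": len(cmp.within), "n_between": len(cmp.between),
                }
            except HgtNetError as exc:
                log.warning("similarity test unavailable: %s", exc)
            log.info("similarity: %d pairs (%.1fs)", len(combined),
                     time.monotonic() - t0)

        if "communities" in stages:
            current = "communities"
            t0 = time.monotonic()
            taxonomy = read_taxonomy(cfg["taxonomy"])
            comms = []
            for sid, net in networks.items():
                comms.extend(communities_mod.detect_communities(
                    net, resolution=cfg["resolution"], seed=cfg["seed"]))
            clusters, pool = communities_mod.cluster_communities(
                comms, max_distance=cfg["hcc_cut"], min_size=cfg["hcc_min_size"])
            communities_mod.label_community_clusters(
                clusters, {sid: m.group for sid, m in metadata.items()})
            rows, comp_rows = [], []
            for c in clusters:
                rows.append({"cluster_id": c.cluster_id, "label": c.label,
                             "n_communities": c.size})
                for rank in ("phylum", "genus"):
                    prof = communities_mod.cluster_composition(c, taxonomy, rank)
                    for taxon, frac in prof.fractions.items():
                        comp_rows.append({"cluster_id": c.cluster_id, "rank": rank,
                                          "taxon": taxon, "fraction": frac})
            _write_tsv(out / "hcc_clusters.tsv", rows)
            _write_tsv(out / "hcc_composition.tsv", comp_rows)
            _write_tsv(out / "hcc_members.tsv", [
                {"cluster_id": c.cluster_id, "sample_id": m.sample_id,
                 "members": ",".join(sorted(m.members))}
                for c in clusters for m in c.communities
            ])
            report["hcc"] = {"n_clusters": len(clusters),
                             "n_unclustered": len(pool),
                             "labels": {str(c.cluster_id): c.label for c in clusters}}
            log.info("communities: %d HCCs (%.1fs)", len(clusters),
                     time.monotonic() - t0)

        if "hec" in stages:
            current = "hec"
            t0 = time.monotonic()
            taxonomy = read_taxonomy(cfg["taxonomy"])
            try:
                clusters, pool = hec_mod.run_hec_analysis(
                    events, metadata, taxonomy,
                    preset=cfg["hec_preset"],
                    min_samples=cfg["hec_min_samples"],
                    min_class_size=cfg["hec_min_class_size"],
                    max_distance=cfg["hec_cut"],
                    bin_size=cfg["bin_size"],
                )
                _write_tsv(out / "hec_clusters.tsv", [
                    {"cluster_id": c.cluster_id, "label": c.label, "n_events": c.size}
                    for c in clusters
                ])
                _write_tsv(out / "hec_composition.tsv", [
                    {"cluster_id": c.cluster_id, "taxon": t_, "fraction": f}
                    for c in clusters
                    for t_, f in (c.composition.fractions if c.composition else {}).items()
                ])
                report["hec"] = {"n_clusters": len(clusters),
                                 "n_unclustered": len(pool),
                                 "labels": {str(c.cluster_id): c.label for c in clusters}}
            except HgtNetError as exc:
                log.warning("hec stage empty: %s", exc)
                report["hec"] = {"n_clusters": 0, "note": str(exc)}
            log.info("hec done (%.1fs)", time.monotonic() - t0)

        if "fusion" in stages:
            current = "fusion"
            t0 = time.monotonic()
            annotations = read_gene_annotations(cfg["annotations"])
            fusions = fusion_mod.detect_fusions(events, annotations)
            _write_tsv(out / "fusions.tsv", [
                {"sample": f.event.sample_id,
                 "genome_a": f.event.genome_a, "pos_a": f.event.pos_a,
                 "gene_a": f.gene_a.gene_id, "product_a": f.gene_a.product,
                 "genome_b": f.event.genome_b, "pos_b": f.event.pos_b,
                 "gene_b": f.gene_b.gene_id, "product_b": f.gene_b.product}
                for f in fusions
            ])
            summary = fusion_mod.summarize_fusion_functions(fusions)
            _write_tsv(out / "fusion_summary.tsv", [
                {"product": p, "n_events": n} for p, n in summary.most_common()
            ])
            report["fusion"] = {"n_fusion_records": len(fusions),
                                "n_fusion_events": summary.total_fusions}
            log.info("fusion: %d events (%.1fs)", summary.total_fusions,
                     time.monotonic() - t0)

    except HgtNetError as exc:
        raise HgtNetError(f"stage {current!r} failed: {exc}") from exc

    report["run"]["elapsed_s"] = round(time.monotonic() - t_all, 2)
    _write_json_atomic(out / "report.json", report)
    return report


def _write_tsv(path: Path, rows: list[dict]) -> None:
    import pandas as pd

    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def _write_json_atomic(path: Path, payload: dict) -> None:
    tmp = path.with_suffix(".json.tmp")
    with tmp.open("w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
    os.replace(tmp, path)
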