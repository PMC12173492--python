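"""End-to-end orchestration: simulate/ingest → networks → vocal statistics.

A run is driven by a single YAML-compatible config dict with explicit seeds
for every stochastic stage.  Outputs are written as CSV/JSON into one bundle
directory together with a manifest (effective config + SHA-256 checksums),
so a rerun with the same config and seeds is byte-identical and a completed
bundle is never recomputed unless forced.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import time

import networkx as nx
import numpy as np
import pandas as pd

from mousebarn import audio, networks, rfid, synth, vocal
from mousebarn.config import SyntheticConfig

logger = logging.getLogger("mousebarn")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "config": {},              # SyntheticConfig overrides
        "year": 2023,
        "days_per_season": 7,
        "recordings_per_season": 1,
        "n_segments": 720,
        "boxes_per_deployment": 4,
    },
    "inputs": None,                # alternatively: paths to existing CSVs
    "analysis": {
        "n_rand_modularity": 50,
        "n_random_smallworld": 20,
        "n_perm_cominute": 1000,
        "n_rand_alignment": 100,
        "bin_width": 5.0,
        "window": 60.0,
        "min_meetings": 4,
        "n_shuffles": 50,
    },
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def resolve_config(config: dict | None) -> dict:
    """Merge a user config over the documented defaults."""
    out = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v
    if config:
        merge(out, config)
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(paths: dict) -> None:
    missing = [k for k, p in paths.items() if not os.path.exists(p)]
    if missing:
        raise FileNotFoundError(
            f"missing input files: {[paths[k] for k in missing]}")


def run_pipeline(config: dict | None, outdir: str,
                 force: bool = False) -> dict:
    """Execute all stages in dependency order; returns the results bundle.

    A bundle directory with a manifest matching this config is returned
    untouched unless ``force``.  Stage failures abort with the failing stage
    named; partial outputs are kept under a ``failed`` marker file.
    """
    config = resolve_config(config)
    os.makedirs(outdir, exist_ok=True)
    manifest_path = os.path.join(outdir, "manifest.json")
    chash = _config_hash(config)
    if not force and os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        if manifest.get("config_hash") == chash:
            logger.info("bundle up to date; skipping (use force to rerun)")
            return manifest
    # input validation happens before any compute or partial output
    if config["inputs"] is not None:
        validate_inputs(config["inputs"])
    results: dict = {"config": config, "config_hash": chash, "stages": {}}
    stage = "validate"
    try:
        outputs: dict[str, str] = {}

        def _write_df(name, df):
            path = os.path.join(outdir, name)
            df.to_csv(path, index=False)
            outputs[name] = path

        def _write_json(name, obj):
            path = os.path.join(outdir, name)
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=1, default=float)
            outputs[name] = path

        # -- stage: data ---------------------------------------------------
        stage = "data"
        t0 = time.time()
        if config["inputs"] is None:
            sim = config["simulate"]
            sc = dict(sim["config"])
            sc.setdefault("seed", config["seed"])
            syn_cfg = SyntheticConfig.from_dict(sc)
            data_dir = os.path.join(outdir, "data")
            paths = synth.generate_dataset(
                syn_cfg, data_dir, year=sim["year"],
                days_per_season=sim["days_per_season"],
                recordings_per_season=sim["recordings_per_season"],
                n_segments=sim["n_segments"],
                boxes_per_deployment=sim["boxes_per_deployment"])
        else:
            paths = dict(config["inputs"])
        stays, stays_qc = rfid.read_stays(paths["stays"])
        detections, det_qc = audio.read_detections(paths["detections"])
        anchors = audio.read_anchors(paths["anchors"])
        recordings = audio.read_recordings(paths["recordings"], anchors)
        layout = pd.read_csv(paths["layout"], dtype={"box_id": str})
        pups = dict(pd.read_csv(paths["pups"],
                                dtype={"recording_id": str})
                    .set_index("recording_id")["n_pups"])
        results["stages"]["data"] = {"qc_stays": stays_qc,
                                     "qc_detections": det_qc,
                                     "seconds": round(time.time() - t0, 2)}

        # -- stage: rfid ---------------------------------------------------
        stage = "rfid"
        t0 = time.time()
        meetings = rfid.detect_meetings(stays)
        summaries = rfid.summarize_all(stays)
        _write_df("mouse_summaries.csv", summaries)
        _write_df("meetings.csv", meetings)
        span = (stays["entry"].min(), stays["exit"].max())
        season_keys = rfid.seasons_in_range(*span)
        occupancy_rows, turnover_rows = [], []
        for label, year in season_keys:
            win = rfid.season_window(label, year)
            for box in layout["box_id"]:
                _, _, occ = rfid.occupancy_series(stays, box, 300.0,
                                                  span=win)
                to = rfid.weekly_turnover(stays, box, win)
                occupancy_rows.append({"season": label, "year": year,
                                       "box_id": box,
                                       "mean_occupants": occ})
                if to is not None:
                    turnover_rows.append({"season": label, "year": year,
                                          "box_id": box, "turnover": to})
        _write_df("box_occupancy.csv", pd.DataFrame(
            occupancy_rows, columns=["season", "year", "box_id",
                                     "mean_occupants"]))
        _write_df("weekly_turnover.csv", pd.DataFrame(
            turnover_rows, columns=["season", "year", "box_id",
                                    "turnover"]))
        results["stages"]["rfid"] = {
            "n_meetings": int(len(meetings)),
            "n_mice": int(stays["mouse_id"].nunique()),
            "seconds": round(time.time() - t0, 2)}

        # -- stage: networks -----------------------------------------------
        stage = "networks"
        t0 = time.time()
        ana = config["analysis"]
        seed = int(config["seed"])
        net_rows, node_tables, comm_tables, decay_rows = [], [], [], []
        for label, year in season_keys:
            win = rfid.season_window(label, year)
            coi = networks.compute_coi(meetings, stays, win)
            g = networks.build_network(coi)
            if g.number_of_edges() < 2:
                continue
            partition, q = networks.detect_communities(g, seed=seed)
            mt = networks.modularity_test(g, ana["n_rand_modularity"],
                                          seed=seed)
            comp = max(len(c) for c in nx.connected_components(g))
            sw = (networks.small_world(g, ana["n_random_smallworld"],
                                       seed=seed)
                  if comp >= 4 else None)
            nm = networks.node_metrics(g, partition)
            nm.insert(0, "season", label)
            nm.insert(1, "year", year)
            node_tables.append(nm)
            cs = networks.community_stats(
                partition, stays, win,
                population_size=int(stays["mouse_id"].nunique()),
                n_boxes=int(len(layout)))
            cs.insert(0, "season", label)
            cs.insert(1, "year", year)
            comm_tables.append(cs)
            pts = networks.box_sharing_vs_distance(stays, layout, win)
            decay = networks.fit_decay(pts) if len(pts) >= 3 else None
            if decay is not None:
                decay_rows.append({"season": label, "year": year,
                                   "a": decay.a, "b": decay.b,
                                   "rss": decay.rss})
            net_rows.append({
                "season": label, "year": year,
                "n_nodes": g.number_of_nodes(),
                "n_edges": g.number_of_edges(),
                "n_communities": len(set(partition.values())),
                "modularity": q, "modularity_null_mean":
                    float(mt.null_q.mean()), "modularity_z": mt.z,
                "small_world_sigma": sw.sigma if sw else float("nan"),
            })
            edges = coi.pairs.rename(columns={"overlap": "overlap_s"})
            path = os.path.join(outdir, f"coi_{label}_{year}.csv")
            edges.to_csv(path, index=False)
            outputs[f"coi_{label}_{year}.csv"] = path
        _write_df("network_summary.csv", pd.DataFrame(
            net_rows, columns=["season", "year", "n_nodes", "n_edges",
                               "n_communities", "modularity",
                               "modularity_null_mean", "modularity_z",
                               "small_world_sigma"]))
        if node_tables:
            _write_df("node_metrics.csv", pd.concat(node_tables,
                                                    ignore_index=True))
        if comm_tables:
            _write_df("community_stats.csv", pd.concat(comm_tables,
                                                       ignore_index=True))
        _write_df("decay_fits.csv", pd.DataFrame(
            decay_rows, columns=["season", "year", "a", "b", "rss"]))
        results["stages"]["networks"] = {
            "n_seasons": len(net_rows),
            "seconds": round(time.time() - t0, 2)}

        # -- stage: vocals -------------------------------------------------
        stage = "vocals"
        t0 = time.time()
        rec_by_id = {r.recording_id: r for r in recordings}
        corrected = []
        for rec_id, sub in detections.groupby("recording_id"):
            rec = rec_by_id.get(str(rec_id))
            if rec is None or rec.anchors is None:
                continue
            corrected.append(audio.correct_clock(sub, rec.anchors))
        events = (pd.concat(corrected, ignore_index=True)
                  if corrected else detections.iloc[0:0])
        glm_rows, presence_rows, cominute_rows = [], [], []
        align_actual = {lbl: [] for lbl in ("entrance", "exit")}
        for rec in recordings:
            counts, _ = audio.bin_segments(events, rec)
            season, _ = rfid.assign_season(rec.start)
            sub_stays = stays[stays["box_id"] == rec.box_id]
            in_span = sub_stays[(sub_stays["entry"] < rec.end)
                                & (sub_stays["exit"] > rec.start)]
            adults = in_span["mouse_id"].nunique()
            males = in_span.drop_duplicates("mouse_id")["sex"].eq(
                "male").sum()
            glm_rows.append({
                "recording_id": rec.recording_id, "season": season,
                "squeak": int(counts["squeak"].sum()),
                "usv": int(counts["usv"].sum()),
                "n_adults": int(adults),
                "sex_ratio": float(males / adults) if adults else 0.5,
                "n_pups": int(pups.get(rec.recording_id, 0)),
                "exposure": rec.n_segments,
            })
            presence_rows.append({
                "recording_id": rec.recording_id, "season": season,
                "pct_minutes_squeak": audio.presence_fraction(counts,
                                                              "squeak"),
                "pct_minutes_usv": audio.presence_fraction(counts, "usv"),
            })
            cm = vocal.cominute_test(counts["squeak"].to_numpy(),
                                     counts["usv"].to_numpy(),
                                     n_perm=ana["n_perm_cominute"],
                                     seed=seed)
            cominute_rows.append({
                "recording_id": rec.recording_id, "season": season,
                "observed_cominutes": cm.observed, "p_value": cm.p_value,
                "t_vs_null": cm.t_vs_null})
            ev_sub = events[events["box_id"] == rec.box_id]
            onsets = ev_sub["onset"].to_numpy(dtype=float)
            entr = in_span["entry"].to_numpy()
            exits = in_span["exit"].to_numpy()
            for kind, times in (("entrance", entr), ("exit", exits)):
                h = vocal.align_to_events(onsets, times,
                                          window=ana["window"],
                                          bin_width=ana["bin_width"])
                align_actual[kind].append(h.counts)
        _write_df("glm_table.csv", pd.DataFrame(glm_rows))
        _write_df("presence_fractions.csv", pd.DataFrame(presence_rows))
        _write_df("cominute_tests.csv", pd.DataFrame(cominute_rows))
        edges = np.arange(-ana["window"], ana["window"] + ana["bin_width"]
                          / 2, ana["bin_width"])
        align_out = {"bin_edges_s": edges.tolist()}
        for kind, stacks in align_actual.items():
            total = (np.sum(stacks, axis=0) if stacks
                     else np.zeros(len(edges) - 1))
            tot = total.sum()
            align_out[f"{kind}_counts"] = np.asarray(total).tolist()
            align_out[f"{kind}_pct"] = (
                (100.0 * total / tot).tolist() if tot > 0
                else [0.0] * (len(edges) - 1))
        _write_json("perievent_histograms.json", align_out)

        glm_table = pd.DataFrame(glm_rows)
        glm_results = {}
        for lbl in ("squeak", "usv"):
            tab = glm_table.rename(columns={lbl: "count"})
            if (len(tab) >= 10 and tab["season"].nunique() >= 2
                    and tab["count"].sum() > 0):
                comp = vocal.fit_vocal_glms(tab)
                glm_results[lbl] = {
                    "best": comp.best,
                    "aic": {m.name: m.aic for m in comp.models.values()},
                    "alpha": {m.name: m.alpha
                              for m in comp.models.values()},
                    "pseudo_r2": {m.name: m.pseudo_r2
                                  for m in comp.models.values()},
                }
        _write_json("glm_comparison.json", glm_results)

        series = vocal.build_pair_series(meetings, events, stays,
                                         recordings,
                                         min_meetings=ana["min_meetings"])
        rho_tab = vocal.all_pair_spearman(series)
        _write_df("pair_spearman.csv", rho_tab)
        pair_summary = {"n_pairs": int(len(rho_tab)),
                        "mean_rho": (float(rho_tab["rho"].mean())
                                     if len(rho_tab) else float("nan"))}
        if len(series) >= 1 and len(rho_tab):
            ctrl = vocal.shuffled_pair_controls(
                series, n_shuffles=ana["n_shuffles"], seed=seed)
            pair_summary["null_mean_rho"] = float(ctrl.null.mean())
            pair_summary["p_right_shifted"] = ctrl.p_greater
        _write_json("pair_summary.json", pair_summary)
        results["stages"]["vocals"] = {
            "n_recordings": len(recordings),
            "n_events_rfid_frame": int(len(events)),
            "seconds": round(time.time() - t0, 2)}

        # -- manifest ------------------------------------------------------
        stage = "manifest"
        results["outputs"] = {name: _checksum(path)
                              for name, path in sorted(outputs.items())}
        with open(manifest_path, "w") as fh:
            json.dump(results, fh, indent=1, default=float)
    except Exception as e:  # noqa: BLE001 - annotate the failing stage
        with open(os.path.join(outdir, "failed"), "w") as fh:
            fh.write(f"stage: {stage}\nerror: {e}\n")
        raise PipelineError(stage, e) from e
    failed_marker = os.path.join(outdir, "failed")
    if os.path.exists(failed_marker):
        os.remove(failed_marker)
    return results


#: report sections and the bundle file each one mirrors
REPORT_SECTIONS = [
    ("Box use summaries", "mouse_summaries.csv"),
    ("Meetings", "meetings.csv"),
    ("Box occupancy", "box_occupancy.csv"),
    ("Weekly turnover", "weekly_turnover.csv"),
    ("Seasonal networks", "network_summary.csv"),
    ("Node metrics", "node_metrics.csv"),
    ("Community statistics", "community_stats.csv"),
    ("Box sharing vs distance fits", "decay_fits.csv"),
    ("Vocal presence fractions", "presence_fractions.csv"),
    ("Squeak/USV co-minute tests", "cominute_tests.csv"),
    ("Peri-event histograms", "perievent_histograms.json"),
    ("Count-model comparison (AIC)", "glm_comparison.json"),
    ("Pair vocal-COI correlations", "pair_spearman.csv"),
]


def report(outdir: str) -> str:
    """Human-readable summary of a results bundle; missing sections are
    flagged as gaps rather than raising."""
    lines = ["mousebarn results bundle", f"directory: {outdir}", ""]
    manifest_path = os.path.join(outdir, "manifest.json")
    gaps = 0
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        lines.append(f"config hash: {manifest['config_hash'][:12]}")
        for name, info in manifest.get("stages", {}).items():
            lines.append(f"stage {name}: {info}")
    else:
        lines.append("GAP: manifest.json missing (incomplete bundle)")
        gaps += 1
    lines.append("")
    for title, fname in REPORT_SECTIONS:
        path = os.path.join(outdir, fname)
        if not os.path.exists(path):
            lines.append(f"GAP: {title} ({fname} missing)")
            gaps += 1
            continue
        if fname.endswith(".csv"):
            try:
                df = pd.read_csv(path)
            except pd.errors.EmptyDataError:
                lines.append(f"{title} [{fname}]: 0 rows")
                continue
            lines.append(f"{title} [{fname}]: {len(df)} rows, "
                         f"columns {list(df.columns)}")
        else:
            with open(path) as fh:
                obj = json.load(fh)
            keys = list(obj) if isinstance(obj, dict) else len(obj)
            lines.append(f"{title} [{fname}]: {keys}")
    lines.append("")
    lines.append(f"flagged gaps: {gaps}")
    return "\n".join(lines)
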