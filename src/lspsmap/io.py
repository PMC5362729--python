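"""On-disk formats: HDF5 map recordings, YAML configs, CSV tables.

HDF5 layout for a simulated map experiment::

    /map/rep_<k>/site_<i>/trace    float32 current (pA)
        attrs: x_um, y_um, flash_onset_ms, flash_duration_ms
    /map/rep_<k> attrs: stimulus_order
    /map/meta attrs: sample_interval_s, t0_s, seed, config (JSON)
    /truth/{site, rep, time_ms, amp_pA}
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import yaml

from lspsmap.synthdata import CircuitConfig, MapRecording

__all__ = ["save_map_h5", "load_map_h5", "load_config", "save_config"]


def save_map_h5(path, recordings: list[MapRecording], config: CircuitConfig):
    with h5py.File(path, "w") as f:
        meta = f.create_group("map/meta")
        meta.attrs["sample_interval_s"] = recordings[0].sample_interval
        meta.attrs["t0_s"] = recordings[0].t0
        meta.attrs["seed"] = config.seed
        meta.attrs["config"] = config.to_json()
        truth_frames = []
        for rec in recordings:
            g = f.create_group(f"map/rep_{rec.repetition_index}")
            g.attrs["stimulus_order"] = rec.stimulus_order
            for s in range(rec.n_sites):
                d = g.create_dataset(f"site_{s}/trace",
                                     data=rec.traces[s].astype(np.float32))
                d.attrs["x_um"] = rec.sites[s, 0]
                d.attrs["y_um"] = rec.sites[s, 1]
                d.attrs["flash_onset_ms"] = rec.flash_onset_ms
                d.attrs["flash_duration_ms"] = rec.flash_duration_ms
                d.attrs["power_density_mw_mm2"] = rec.power_density
            t = rec.truth.copy()
            t["rep"] = rec.repetition_index
            truth_frames.append(t)
        truth = pd.concat(truth_frames, ignore_index=True)
        tg = f.create_group("truth")
        tg.create_dataset("site", data=truth["site"].to_numpy(dtype=np.int32))
        tg.create_dataset("rep", data=truth["rep"].to_numpy(dtype=np.int32))
        tg.create_dataset("time_ms", data=truth["time_ms"].to_numpy(dtype=float))
        tg.create_dataset("amp_pA", data=truth["amp_pA"].to_numpy(dtype=float))


def load_map_h5(path):
    """Load (recordings, config) from the layout written by save_map_h5."""
    with h5py.File(path, "r") as f:
        meta = f["map/meta"]
        config = CircuitConfig.from_dict(json.loads(meta.attrs["config"]))
        sample_interval = float(meta.attrs["sample_interval_s"])
        t0 = float(meta.attrs["t0_s"])
        truth = pd.DataFrame({k: f["truth"][k][()] for k in
                              ("site", "rep", "time_ms", "amp_pA")})
        recordings = []
        rep_names = sorted((k for k in f["map"] if k.startswith("rep_")),
                           key=lambda k: int(k.split("_")[1]))
        for name in rep_names:
            rep = int(name.split("_")[1])
            g = f["map"][name]
            site_names = sorted((k for k in g if k.startswith("site_")),
                                key=lambda k: int(k.split("_")[1]))
            sites, traces = [], []
            flash_onset = flash_dur = power = 0.0
            for sn in site_names:
                d = g[sn]["trace"]
                traces.append(d[()].astype(float))
                sites.append((d.attrs["x_um"], d.attrs["y_um"]))
                flash_onset = float(d.attrs["flash_onset_ms"])
                flash_dur = float(d.attrs["flash_duration_ms"])
                power = float(d.attrs.get("power_density_mw_mm2", 0.0))
            recordings.append(MapRecording(
                repetition_index=rep,
                sites=np.asarray(sites),
                traces=np.vstack(traces),
                sample_interval=sample_interval,
                t0=t0,
                flash_onset_ms=flash_onset,
                flash_duration_ms=flash_dur,
                power_density=power,
                stimulus_order=np.asarray(g.attrs["stimulus_order"], dtype=int),
                truth=truth[truth["rep"] == rep].drop(columns="rep").reset_index(drop=True),
            ))
    return recordings, config


def load_config(path) -> CircuitConfig:
    """CircuitConfig from a YAML/JSON file mirroring its field names."""
    with open(path) as f:
        return CircuitConfig.from_dict(yaml.safe_load(f))


def save_config(path, config: CircuitConfig):
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)
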