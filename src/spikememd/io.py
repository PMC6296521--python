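"""Spike-table TSV and result-container I/O."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import GeneratorParams, ProtocolConfig
from .synthetic import SpikeDataset

__all__ = ["write_spike_tsv", "read_spike_tsv", "save_results_hdf5"]

_COLUMNS = ["animal_id", "electrode_id", "isi_s", "trial_index", "spike_time_s"]


def write_spike_tsv(dataset: SpikeDataset, path, protocol_sidecar: bool = True) -> None:
    """Write the spike table as TSV plus a protocol JSON sidecar."""
    path = Path(path)
    dataset.spikes.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if protocol_sidecar:
        dataset.protocol.to_json(path.with_suffix(".protocol.json"))


def read_spike_tsv(path, protocol: ProtocolConfig | None = None) -> SpikeDataset:
    """Read a spike TSV, validating the header and every row.

    Malformed rows (non-numeric times, negative trial indices) are rejected
    with their 1-based line numbers. If no protocol is given, the JSON
    sidecar written next to the table is required.
    """
    path = Path(path)
    if protocol is None:
        sidecar = path.with_suffix(".protocol.json")
        if not sidecar.exists():
            raise FileNotFoundError(f"no protocol given and no sidecar at {sidecar}")
        protocol = ProtocolConfig.from_json(sidecar)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_lines: list[int] = []
    parsed = {}
    for col, kind in [("electrode_id", int), ("isi_s", float), ("trial_index", int),
                      ("spike_time_s", float)]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (df[col].isna())
        if kind is int:
            bad |= vals.notna() & (vals % 1 != 0)
        bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-based
        parsed[col] = vals
    neg = parsed["trial_index"] < 0
    bad_lines.extend((df.index[neg.fillna(False)] + 2).tolist())
    if bad_lines:
        raise ValueError(f"{path}: malformed rows at lines {sorted(set(bad_lines))}")
    # final conversion via astype(float): correctly-rounded string parsing,
    # so write -> read round-trips bit-exactly
    out = pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "electrode_id": df["electrode_id"].astype(float).astype(int),
            "isi_s": df["isi_s"].astype(float),
            "trial_index": df["trial_index"].astype(float).astype(int),
            "spike_time_s": df["spike_time_s"].astype(float),
        }
    )
    return SpikeDataset(spikes=out, protocol=protocol, provenance={"path": str(path)})


def save_results_hdf5(results, path) -> None:
    """Persist a pipeline result container to one HDF5 file.

    Groups per stage and animal; the full run configuration is embedded as a
    JSON attribute so every numeric output is traceable to its settings.
    """
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = json.dumps(results.config.to_dict())
        for animal, res in results.per_animal.items():
            g = f.create_group(f"animals/{animal}")
            g.create_dataset("imf_freq_mean", data=res.imf_freq_mean)
            g.create_dataset("imf_freq_sd", data=res.imf_freq_sd)
            for isi, win in res.norm_windows.items():
                gg = g.create_group(f"isi_{isi:g}/windows")
                gg.create_dataset("normalized", data=win.data)
                gg.attrs["bin_width"] = win.bin_width
                gg.attrs["window"] = win.window
            for isi, modes in res.evoked_modes.items():
                g.create_dataset(f"isi_{isi:g}/evoked_modes", data=modes)
            if res.trial_ia is not None:
                for isi, ia in res.trial_ia.items():
                    g.create_dataset(f"isi_{isi:g}/trial_ia", data=ia)
            for isi, cv in res.cv.items():
                gc = g.create_group(f"isi_{isi:g}/cv")
                gc.create_dataset("cv", data=cv.cv)
                gc.create_dataset("times", data=cv.times)
            for pair, dm in res.maps.items():
                gm = g.create_group(f"maps/{pair}")
                gm.create_dataset("p", data=dm.p)
                gm.create_dataset("q", data=dm.q)
                gm.create_dataset("times", data=dm.times)
                gm.attrs["pi0"] = dm.pi0
            for pair, rc in res.rate_comparisons.items():
                gr = g.create_group(f"rates/{pair}")
                gr.create_dataset("p", data=rc.p)
                gr.create_dataset("q", data=rc.q)
                gr.attrs["window_p"] = rc.window_p
            if res.distances is not None:
                gd = g.create_group("phasespace")
                gd.create_dataset("pairwise", data=res.distances.pairwise)
                gd.create_dataset("linkage", data=res.distances.linkage)
                gd.attrs["newick"] = res.distances.to_newick()
                for isi, prof in res.distances.profiles.items():
                    gd.create_dataset(f"distance_isi_{isi:g}", data=prof)
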