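"""Plain-text serialization of sessions.

A session directory holds:

* ``syllables.tsv`` — instance_index, syllable, onset_frame, duration_frames, da_amp
* ``photometry.tsv`` — frame, signal, reference (plus derived columns if present)
* ``kinematics.tsv`` — frame, velocity_2d, angular_velocity, height_velocity, acceleration
* ``stim.tsv`` — target-instance stim/catch flags (if a schedule exists)
* ``truth.json`` — generator parameters (ground truth), if known
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .generate import GenerativeParams, KinematicSeries, SessionBundle, StimSchedule
from .photometry import PhotometryTrace

__all__ = ["save_session", "load_session"]


def save_session(session: SessionBundle, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "instance_index": np.arange(session.n_steps),
        "syllable": session.labels,
        "onset_frame": session.onset_frames,
        "duration_frames": session.durations_frames,
        "da_amp": session.da_amplitudes,
    }).to_csv(out / "syllables.tsv", sep="\t", index=False)
    if session.photometry is not None:
        ph = session.photometry
        cols = {"frame": np.arange(ph.n_samples),
                "signal": ph.raw_signal, "reference": ph.raw_reference}
        for name in ("dff_signal", "dff_reference", "referenced", "zscored"):
            v = getattr(ph, name)
            if v is not None:
                cols[name] = v
        pd.DataFrame(cols).to_csv(out / "photometry.tsv", sep="\t", index=False)
        (out / "photometry.json").write_text(json.dumps(
            {"sampling_rate_hz": ph.sampling_rate_hz, "provenance": ph.provenance}
        ))
    if session.kinematics is not None:
        k = session.kinematics
        pd.DataFrame({
            "frame": np.arange(k.n_frames),
            "velocity_2d": k.velocity_2d,
            "angular_velocity": k.angular_velocity,
            "height_velocity": k.height_velocity,
            "acceleration": k.acceleration,
        }).to_csv(out / "kinematics.tsv", sep="\t", index=False)
    if session.stim is not None:
        st = session.stim
        pd.DataFrame({
            "target_instance": np.arange(st.stim_instance_flags.size),
            "stim": st.stim_instance_flags.astype(int),
            "catch": st.catch_instance_flags.astype(int),
        }).to_csv(out / "stim.tsv", sep="\t", index=False)
        (out / "stim.json").write_text(json.dumps({
            "target": int(st.target), "phase": st.phase,
            "stim_prob": st.stim_prob, "extra_da": st.extra_da,
        }))
    meta = {"mouse": session.mouse, "session": session.session}
    if session.truth is not None:
        meta["truth"] = session.truth.to_dict()
    (out / "truth.json").write_text(json.dumps(meta))
    return out


def load_session(in_dir) -> SessionBundle:
    d = Path(in_dir)
    syl = pd.read_csv(d / "syllables.tsv", sep="\t")
    photometry = kinematics = stim = truth = None
    if (d / "photometry.tsv").exists():
        ph = pd.read_csv(d / "photometry.tsv", sep="\t")
        meta = json.loads((d / "photometry.json").read_text()) \
            if (d / "photometry.json").exists() else {"sampling_rate_hz": 30.0,
                                                      "provenance": []}
        photometry = PhotometryTrace(
            meta["sampling_rate_hz"], ph["signal"].to_numpy(), ph["reference"].to_numpy()
        )
        photometry.provenance = meta.get("provenance", [])
        for name in ("dff_signal", "dff_reference", "referenced", "zscored"):
            if name in ph:
                setattr(photometry, name, ph[name].to_numpy())
    if (d / "kinematics.tsv").exists():
        k = pd.read_csv(d / "kinematics.tsv", sep="\t")
        kinematics = KinematicSeries(
            k["velocity_2d"].to_numpy(), k["angular_velocity"].to_numpy(),
            k["height_velocity"].to_numpy(), k["acceleration"].to_numpy(),
        )
    if (d / "stim.tsv").exists():
        st = pd.read_csv(d / "stim.tsv", sep="\t")
        sm = json.loads((d / "stim.json").read_text())
        stim = StimSchedule(
            target=sm["target"],
            stim_instance_flags=st["stim"].to_numpy(bool),
            catch_instance_flags=st["catch"].to_numpy(bool),
            phase=sm["phase"], stim_prob=sm["stim_prob"], extra_da=sm["extra_da"],
        )
    meta = json.loads((d / "truth.json").read_text()) if (d / "truth.json").exists() else {}
    if "truth" in meta:
        truth = GenerativeParams.from_dict(meta["truth"])
    return SessionBundle(
        labels=syl["syllable"].to_numpy(int),
        onset_frames=syl["onset_frame"].to_numpy(int),
        durations_frames=syl["duration_frames"].to_numpy(int),
        da_amplitudes=syl["da_amp"].to_numpy(float),
        photometry=photometry, kinematics=kinematics, stim=stim, truth=truth,
        mouse=meta.get("mouse", "m0"), session=meta.get("session", "s0"),
    )
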