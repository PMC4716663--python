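"""Closed-loop engine: builds the full four-area model and runs the
information-based spike-exchange step.

Wiring
------
The four cortical areas form a ring.  ``area_names`` lists them in the
feedback (traversal / synfire propagation) order, M1 -> M_sup -> S_sec ->
S1 -> M1; feed-forward relays run the reverse direction (S1 -> S_sec ->
M_sup -> M1 -> S1).  The two frontal areas (M_sup, M1) receive their
feed-forward thalamic relay through the basal-ganglia gate; the two
sensory areas relay ungated.

Per 1-ms step, in fixed order:

1. layer 5 advances under the gain ``U`` computed from the previous
   layer-2/3 outputs, and its plasticity is applied;
2. the trailing spike-count windows (length tau_X) are updated;
3. the striatum advances under corticostriatal drive; burst outputs P and
   their derivative sign are read out;
4. the pallido-thalamic gate G_hat = H[D P] is evaluated for gated areas;
5. thalamic relay (x_FF = G_hat * M_FF x_hat_FF) and layer-4 combination
   (x_hat_I = x_FB + x_FF) run per area;
6. each area's layer-2/3 Infomax network does a forward pass and learns;
7. corticostriatal STDP is applied under the current GABA and dopamine
   conditions;
8. dopamine neurons advance under summed MSN inhibition;
9. dopamine spikes stamp modulation windows onto their synapses.

This order is part of the model definition and is never reordered.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dopamine as da
from . import infomax as im
from . import layer5 as l5
from . import striatum as st
from .config import ModelConfig

__all__ = [
    "GrandLoopModel",
    "SpikeWindow",
    "window_rates",
    "forward_gate",
    "relay",
    "combine_layer4",
    "ach_gain",
    "lognormal_mixing",
    "write_artifacts",
]


# ---------------------------------------------------------------------------
# interface primitives

def window_rates(raster: np.ndarray, t: int, tau_X: int) -> np.ndarray:
    """Per-unit spike counts over the trailing ``tau_X`` steps of a
    (time x unit) raster, ending at step ``t`` inclusive.  Before warm-up
    (t < tau_X - 1) the counts cover the available history."""
    lo = max(0, t + 1 - tau_X)
    return raster[lo:t + 1].sum(axis=0).astype(float)


def forward_gate(D: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Pallido-thalamic gate: G_hat_j = H(sum_i D[j,i] P_i), with
    H(0) = 0 — tonic pallidal inhibition closes the relay at exact
    balance; disinhibition must be strictly positive."""
    return (D @ P > 0.0).astype(float)


def relay(x_hat_FF: np.ndarray, M_FF: np.ndarray,
          Ghat: np.ndarray) -> np.ndarray:
    """Thalamic relay: elementwise gate on the mixed feed-forward rates."""
    theta = M_FF @ x_hat_FF
    if Ghat.shape != theta.shape:
        raise ValueError("gate / relay size mismatch")
    return Ghat * theta


def combine_layer4(x_FB: np.ndarray, x_FF: np.ndarray,
                   sensory: np.ndarray | None = None) -> np.ndarray:
    """Layer-4 input combination; the optional sensory term is an unused
    extension hook."""
    out = x_FB + x_FF
    if sensory is not None:
        out = out + sensory
    return out


def ach_gain(y: np.ndarray, Ach: float) -> np.ndarray:
    """Cholinergic gain on layer-5 feedback integration:
    U_j = [1 - Ach (1 - y_j)] / [1 - Ach/2].  Unity everywhere at Ach = 0;
    range (1-Ach, 1+Ach)/(1-Ach/2) otherwise, with mean(U) = 1 whenever
    mean(y) = 1/2."""
    if not 0.0 <= Ach <= 1.0:
        raise ValueError("Ach must lie in [0, 1]")
    return (1.0 - Ach * (1.0 - np.asarray(y, dtype=float))) / (1.0 - Ach / 2.0)


def lognormal_mixing(rng: np.random.Generator, shape: tuple[int, int]
                     ) -> np.ndarray:
    """Strictly positive mixing matrix with unit mean and unit standard
    deviation of the lognormal distribution itself (sigma^2 = ln 2,
    mu = -ln(2)/2 in log space)."""
    sigma2 = np.log(2.0)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


class SpikeWindow:
    """Ring buffer maintaining trailing spike counts per unit."""

    def __init__(self, n_units: int, tau: int):
        self.buf = np.zeros((tau, n_units), dtype=np.int8)
        self.counts = np.zeros(n_units, dtype=np.int64)
        self.ptr = 0
        self.tau = tau

    def push(self, spikes: np.ndarray) -> None:
        self.counts += spikes - self.buf[self.ptr]
        self.buf[self.ptr] = spikes
        self.ptr = (self.ptr + 1) % self.tau


# ---------------------------------------------------------------------------
# full model

@dataclass
class Recording:
    layer5: np.ndarray | None = None      # (T, N_E) int8
    dopamine: np.ndarray | None = None    # (T, N_DA) int8
    x_f: np.ndarray | None = None         # (T, N_Str)
    U: np.ndarray | None = None           # (T, N_E)
    ach: np.ndarray | None = None         # (T,)
    t0: int = 0


class GrandLoopModel:
    """The assembled closed-loop model.

    Build with :meth:`develop` (which self-organizes layer 5 and wires
    everything downstream of the emergent areas), then drive with
    :meth:`run_phase`.  All randomness derives from the constructor seed
    through named child streams, so identical (config, seed) pairs replay
    bit-for-bit.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.config.validate()
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        (self._ss_l5, self._ss_str, self._ss_cstr, self._ss_da,
         self._ss_mix, self._ss_ach) = ss.spawn(6)
        self.layer5 = l5.init_layer5(self.config.layer5,
                                     self._ss_l5.generate_state(1)[0])
        self.t = 0
        self.built = False

    # -- construction ------------------------------------------------------

    def develop(self, n_steps: int | None = None) -> "GrandLoopModel":
        """Phase 1: self-organize the layer-5 ring, then wire the rest of
        the model around the emergent areas."""
        cfg = self.config
        if n_steps is None:
            n_steps = cfg.loop.develop_steps
        l5.develop_ring(self.layer5, n_steps)
        self.layer5.area_names = tuple(cfg.loop.area_names)
        self._build()
        self.t = n_steps
        return self

    def _build(self) -> None:
        cfg = self.config
        n_areas = cfg.layer5.N_A
        per_area = cfg.layer5.N_E // n_areas
        labels = self.layer5.area_label
        self.area_units = [np.flatnonzero(labels == k) for k in range(n_areas)]
        names = list(cfg.loop.area_names)
        self.gated = [names[k] in cfg.loop.gated_areas for k in range(n_areas)]
        # feedback source = ring predecessor, feed-forward source = successor
        self.fb_source = [(k - 1) % n_areas for k in range(n_areas)]
        self.ff_source = [(k + 1) % n_areas for k in range(n_areas)]

        mix_rng = np.random.default_rng(self._ss_mix.generate_state(1)[0])
        self.M_FB, self.M_FF = [], []
        for k in range(n_areas):
            n_in_fb = self.area_units[self.fb_source[k]].size
            n_in_ff = self.area_units[self.ff_source[k]].size
            n_out = self.area_units[k].size
            self.M_FB.append(lognormal_mixing(mix_rng, (n_out, n_in_fb)))
            self.M_FF.append(lognormal_mixing(mix_rng, (n_out, n_in_ff)))

        self.infomax = []
        im_seeds = self._ss_mix.spawn(n_areas)
        for k in range(n_areas):
            self.infomax.append(im.init_infomax(
                self.area_units[k].size, cfg.infomax,
                im_seeds[k].generate_state(1)[0]))

        # striatum: MSN home areas alternate over the gated areas so both
        # pathways (D1 first half, D2 second half) cover both frontal areas
        self.striatum = st.init_striatum(
            cfg.striatum, self._ss_str.generate_state(1)[0])
        gated_idx = [k for k in range(n_areas) if self.gated[k]]
        n_msn = cfg.striatum.N_Str
        self.msn_home = np.array(
            [gated_idx[i % len(gated_idx)] for i in range(n_msn)])
        pools = []
        for i in range(n_msn):
            k = self.msn_home[i]
            areas = {k, self.fb_source[k], self.ff_source[k]}
            pools.append(np.concatenate(
                [self.area_units[m] for m in sorted(areas)]))
        self.cstr = st.build_corticostriatal(
            cfg.striatum, self._ss_cstr.generate_state(1)[0],
            pools, cfg.dopamine.N_DA)

        # pallido-thalamic matrices: relay neurons of each gated area draw
        # N_Str_Th MSNs from those gating that area; sign by pathway type
        d_rng = np.random.default_rng(self._ss_cstr.generate_state(2)[-1])
        self.D = [None] * n_areas
        for k in gated_idx:
            candidates = np.flatnonzero(self.msn_home == k)
            D = np.zeros((self.area_units[k].size, n_msn))
            for j in range(D.shape[0]):
                picks = d_rng.choice(candidates, size=cfg.loop.N_Str_Th,
                                     replace=False)
                D[j, picks] = np.where(self.striatum.msn_type[picks], 1.0, -1.0)
            self.D[k] = D

        self.dopamine = da.init_dopamine(
            cfg.dopamine, self._ss_da.generate_state(1)[0], n_msn=n_msn)
        self.window = SpikeWindow(cfg.layer5.N_E, cfg.loop.tau_X)
        self._ach_rng = np.random.default_rng(self._ss_ach.generate_state(1)[0])
        self._U = np.ones(cfg.layer5.N_E)
        self.built = True

    # -- stepping ----------------------------------------------------------

    def gains(self, ach: float) -> np.ndarray:
        """Assemble the per-unit layer-5 gain vector from the current
        layer-2/3 outputs of every area."""
        U = np.ones(self.config.layer5.N_E)
        for k, units in enumerate(self.area_units):
            U[units] = ach_gain(self.infomax[k].y, ach)
        return U

    def step(self, ach: float | None = None) -> dict:
        """One closed-loop 1-ms iteration; returns the step's observables."""
        if not self.built:
            raise RuntimeError("model must be developed/built before stepping")
        cfg = self.config
        if ach is None:
            ach = cfg.loop.Ach
        try:
            return self._step_inner(ach)
        except Exception as exc:
            exc.args = (f"[step t={self.t}] {exc.args[0] if exc.args else ''}",
                        *exc.args[1:])
            raise

    def _step_inner(self, ach: float) -> dict:
        cfg = self.config
        # (1) layer 5 under layer-2/3 gain
        self._U = self.gains(ach)
        prev = self.layer5.x.copy()
        prev_inhib = self.layer5.y_I.copy()
        _, spikes = l5.step_layer5(self.layer5, self._U)
        l5.apply_layer5_plasticity(self.layer5, prev, spikes, prev_inhib)
        # (2) trailing windows
        self.window.push(spikes)
        # (3) striatum
        drive = st.cortical_drive(self.cstr, spikes)
        st.step_striatum(self.striatum, drive)
        P, dP = st.burst_output(self.striatum)
        # (4)-(5) gate, relay, layer-4 combination; (6) layer 2/3
        counts = self.window.counts.astype(float)
        gates = {}
        for k in range(cfg.layer5.N_A):
            x_hat_FB = counts[self.area_units[self.fb_source[k]]]
            x_FB = self.M_FB[k] @ x_hat_FB
            x_hat_FF = counts[self.area_units[self.ff_source[k]]]
            if self.gated[k]:
                Ghat = forward_gate(self.D[k], P)
            else:
                Ghat = np.ones(self.area_units[k].size)
            gates[k] = Ghat
            x_FF = relay(x_hat_FF, self.M_FF[k], Ghat)
            x_hat_I = combine_layer4(x_FB, x_FF)
            im.infomax_forward(self.infomax[k], x_hat_I)
            im.infomax_learn(self.infomax[k])
        # (7) corticostriatal STDP
        st.corticostriatal_stdp(self.cstr, spikes, dP, self.striatum.z_f,
                                self.striatum.msn_type, float(self.t))
        # (8) dopamine
        I_e = da.striatal_input(self.dopamine, P)
        _, da_spikes = da.step_dopamine(self.dopamine, I_e)
        # (9) dopamine stamping
        da.stamp_dopamine(self.cstr, da_spikes, float(self.t),
                          cfg.loop.tau_DA)
        self.t += 1
        return {"spikes": spikes, "da_spikes": da_spikes, "P": P,
                "U": self._U, "gates": gates, "ach": ach}

    def run_phase(self, n_steps: int, ach: float | None = None,
                  bias_phase: bool = False,
                  record_last: int = 0) -> Recording:
        """Run ``n_steps`` closed-loop iterations.

        ``bias_phase=True`` resamples Ach each step from the positive half
        of a unit normal (clipped to 1, since the gain formula requires
        Ach <= 1).  ``record_last`` keeps rasters/traces of the final
        that-many steps.
        """
        cfg = self.config
        keep = min(record_last, n_steps)
        rec = Recording(t0=self.t + n_steps - keep)
        if keep:
            rec.layer5 = np.zeros((keep, cfg.layer5.N_E), dtype=np.int8)
            rec.dopamine = np.zeros((keep, cfg.dopamine.N_DA), dtype=np.int8)
            rec.x_f = np.zeros((keep, cfg.striatum.N_Str))
            rec.U = np.zeros((keep, cfg.layer5.N_E))
            rec.ach = np.zeros(keep)
        for i in range(n_steps):
            if bias_phase:
                ach_t = min(abs(self._ach_rng.normal()), 1.0)
            else:
                ach_t = cfg.loop.Ach if ach is None else ach
            out = self.step(ach_t)
            j = i - (n_steps - keep)
            if keep and j >= 0:
                rec.layer5[j] = out["spikes"]
                rec.dopamine[j] = out["da_spikes"]
                rec.x_f[j] = self.striatum.x_f
                rec.U[j] = out["U"]
                rec.ach[j] = ach_t
        return rec

    def checkpoint(self) -> "GrandLoopModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# artifact writing

def write_artifacts(outdir: str | Path, model: GrandLoopModel,
                    rec: Recording) -> dict:
    """Write run artifacts: spike events as columnar CSV, continuous traces
    and weight matrices as HDF5, and a JSON manifest with the config hash
    and seed.  Returns the manifest."""
    import h5py
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    frames = []
    for name, arr in (("layer5", rec.layer5), ("dopamine", rec.dopamine)):
        if arr is None:
            continue
        t_idx, unit = np.nonzero(arr)
        frames.append(pd.DataFrame({
            "time_ms": t_idx + rec.t0, "unit_id": unit, "population": name}))
    spikes = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["time_ms", "unit_id", "population"]))
    spikes.to_csv(outdir / "spikes.csv", index=False)

    with h5py.File(outdir / "traces.h5", "w") as h5:
        if rec.x_f is not None:
            h5.create_dataset("x_f", data=rec.x_f, compression="gzip")
            h5.create_dataset("U", data=rec.U, compression="gzip")
            h5.create_dataset("ach", data=rec.ach)
        h5.attrs["t0"] = rec.t0
        g = h5.create_group("weights")
        g.create_dataset("W_EE", data=model.layer5.W_EE, compression="gzip")
        g.create_dataset("W_CStr", data=np.where(
            model.cstr.active, model.cstr.w, 0.0))
        g.create_dataset("W_Str", data=model.striatum.W_Str)
        h5.create_dataset("area_label", data=model.layer5.area_label)
        h5.create_dataset("msn_type",
                          data=model.striatum.msn_type.astype(np.int8))

    cfg_json = json.dumps(model.config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "seed": model.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "steps_completed": model.t,
        "recorded_steps": 0 if rec.layer5 is None else int(len(rec.layer5)),
        "files": ["spikes.csv", "traces.h5"],
        "area_names": list(model.layer5.area_names),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
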