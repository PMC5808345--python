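"""Model parameters: membrane currents, pumps/exchangers, SR release and buffers.

The control values below define the baseline hiPSC-CM phenotype of the
package: a small, T-tubule-free cell whose automaticity is driven by
rhythmic SR Ca2+ release ("calcium clock") coupled to the sarcolemma
through the electrogenic Na+/Ca2+ exchanger.  Current formulations follow
the standard Hodgkin-Huxley conventions of the human ventricular/hiPSC
modelling lineage; values marked "inherited" in the config export were
taken from the respective source formulations rather than refit.

Internal units throughout: mV, ms, mM, um, pA/pF.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = ["Parameters", "PARAM_ORDER", "SCALE_TARGETS", "UnknownTargetError"]


class UnknownTargetError(KeyError):
    """Raised by :meth:`Parameters.scaled` for an unrecognized target name."""


@dataclass(frozen=True)
class Parameters:
    # -- geometry / bookkeeping ------------------------------------------
    cm: float = 60.0              # membrane capacitance, pF
    vol_cyto_frac: float = 0.65   # Ca-accessible fraction of geometric volume
    vol_sr_frac: float = 0.06    # SR volume as fraction of geometric volume

    # -- extracellular milieu (mM) ---------------------------------------
    nao: float = 140.0
    ko: float = 5.4
    cao: float = 1.8

    # -- maximum conductances / rates (nS/pF or pA/pF) -------------------
    g_na: float = 12.0            # fast Na+ current
    g_cal: float = 0.10           # L-type Ca2+ current (ohmic, E_app = +60 mV)
    g_to: float = 0.06            # transient outward K+
    g_kr: float = 0.17            # rapid delayed rectifier
    g_ks: float = 0.02            # slow delayed rectifier
    g_k1: float = 1.42            # inward rectifier (weak in hiPSC-CMs)
    g_f: float = 0.01             # funny current
    g_bna: float = 0.0008         # background Na+
    g_bca: float = 0.002        # background Ca2+
    g_pca: float = 0.06           # sarcolemmal Ca2+ pump, max density pA/pF
    p_nak: float = 3.0            # Na+/K+ pump, max density pA/pF
    k_ncx: float = 4000.0         # Na+/Ca2+ exchanger scaling, pA/pF

    # -- I_Na variant hooks (Brugada transformation) ---------------------
    na_avail_shift: float = 0.0   # mV shift of steady-state inactivation (+ = leftward)
    na_tauh_scale: float = 1.0    # fast recovery-from-inactivation slowing
    na_tauj_scale: float = 1.0    # slow recovery-from-inactivation slowing

    # -- I_CaL Ca-dependent inactivation ---------------------------------
    kfca: float = 0.0005          # half-inactivation sub-sarcolemmal Ca (mM)

    # -- cytosolic Ca2+ diffusion ----------------------------------------
    d_ca: float = 0.07            # effective diffusion coefficient, um^2/ms

    # -- SERCA ------------------------------------------------------------
    serca_vmax: float = 2.6e-4    # max uptake, mM/ms (cytosol-referenced)
    serca_km: float = 6.0e-4      # half-saturation, mM
    serca_hill: float = 1.8
    serca_kleak: float = 1.0e-5   # SR->cytosol leak coefficient, 1/ms

    # -- RyR release (three spatial sites share gating law) --------------
    ryr_nu: float = 1.0e-2         # release rate coefficient, 1/ms
    ryr_scale_c: float = 1.0      # per-site density scaling (central region)
    ryr_scale_p2: float = 1.3     # peripheral site at 2 um depth
    ryr_scale_p4: float = 1.0     # peripheral site at 4 um depth
    ryr_ka_min: float = 8.0e-5    # activation half-point at full SR load, mM
    ryr_ka_max: float = 1.6e-4    # activation half-point at empty SR, mM
    ryr_kasr: float = 1.10        # SR-load sensitization half-point, mM
    ryr_hsr: float = 12.0          # Hill coefficient of SR-load sensitization
    ryr_ha: float = 40.0           # Hill coefficient of cytosolic activation
    ryr_tau_act: float = 3.0      # activation gate time constant, ms
    ryr_kw: float = 0.5          # SR refill level required to re-arm a site, mM
    ryr_tau_inact: float = 50.0   # maximum continuous open duration of a site, ms
    ryr_tau_rec: float = 200.0    # refractory period before a site may re-arm, ms
    ryr_klum: float = 0.2        # luminal gating half-point of release flux, mM
    ryr_whyst: float = 0.41        # hysteresis: inactivation midpoint as fraction of ryr_kw
    ryr_carest: float = 3.0e-4    # local Ca below which a shut site may re-arm, mM

    # -- IP3R (constitutive; fixed IP3, no PLC dynamics) ------------------
    ip3_nu: float = 1.0e-3         # release rate coefficient, 1/ms
    ip3_po: float = 1.0e-3          # constitutive open probability

    # -- cytosolic buffers (explicit mass-action kinetics) ----------------
    # species 1: calmodulin-like fast buffer
    buf1_tot: float = 0.024       # mM
    buf1_kon: float = 34.0        # 1/(mM ms)
    buf1_koff: float = 0.238      # 1/ms   (Kd = 7.0 uM)
    # species 2: troponin/SR-membrane-site-like slow buffer
    buf2_tot: float = 0.25
    buf2_kon: float = 32.7
    buf2_koff: float = 0.0196     # Kd = 0.6 uM
    # Fluo-4 dye: only present in the Ca-injection assay (2 uM, Kd 335 nM)
    fluo_tot: float = 0.0
    fluo_kon: float = 80.0
    fluo_koff: float = 0.0268

    # -- SR luminal buffering (calsequestrin, rapid-equilibrium) ----------
    csq_tot: float = 0.5          # mM
    csq_kd: float = 0.6           # mM

    # -- misc -------------------------------------------------------------
    if_na_frac: float = 0.42      # Na+ fraction of the funny current
    stim_k_assign: float = 1.0    # stimulus charge booked against K+ (convention)

    # ---------------------------------------------------------------------
    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_ORDER], dtype=np.float64)

    @classmethod
    def from_array(cls, arr) -> "Parameters":
        return cls(**{n: float(v) for n, v in zip(PARAM_ORDER, arr)})

    def replace(self, **kw) -> "Parameters":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in PARAM_ORDER}

    def scaled(self, target: str, factor: float) -> "Parameters":
        """Return a copy with the named current/pump/release pathway scaled.

        ``factor`` multiplies the maximum conductance / turnover rate, so a
        fractional block ``f`` corresponds to ``factor = 1 - f``.
        """
        try:
            fields = SCALE_TARGETS[target]
        except KeyError:
            raise UnknownTargetError(
                f"unknown scaling target {target!r}; valid: {sorted(SCALE_TARGETS)}"
            ) from None
        return self.replace(**{f: getattr(self, f) * factor for f in fields})


PARAM_ORDER = tuple(f.name for f in dataclasses.fields(Parameters))

#: named components accepted by Parameters.scaled / Model.scale
SCALE_TARGETS = {
    "I_Na": ("g_na",),
    "I_CaL": ("g_cal",),
    "I_to": ("g_to",),
    "I_Kr": ("g_kr",),
    "I_Ks": ("g_ks",),
    "I_K1": ("g_k1",),
    "I_f": ("g_f",),
    "NCX": ("k_ncx",),
    "NKA": ("p_nak",),
    "SERCA": ("serca_vmax",),
    "RyR": ("ryr_nu",),
    "PMCA": ("g_pca",),
    "backgrounds": ("g_bna", "g_bca"),
}
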