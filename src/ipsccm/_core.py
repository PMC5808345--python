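"""Compiled numerical core: right-hand side and time stepper.

Single source of truth for the model physics.  The right-hand side fills,
besides the state derivative, per-gate (x_inf, tau) pairs so the stepper can
advance every Hodgkin-Huxley-type gate with the exact exponential
(Rush-Larsen) update; concentrations and membrane potential use forward
Euler with a rate-adapted step.  All quantities: mV, ms, mM, um, pA/pF.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .parameters import PARAM_ORDER

# ---------------------------------------------------------------------------
# physical constants
FARADAY = 96485.33212  # C/mol
RTF = 26.713           # mV at 310 K

# parameter indices (frozen into the compiled code as globals)
_P = {n: i for i, n in enumerate(PARAM_ORDER)}
P_CM = _P["cm"]; P_VCYT = _P["vol_cyto_frac"]; P_VSR = _P["vol_sr_frac"]
P_NAO = _P["nao"]; P_KO = _P["ko"]; P_CAO = _P["cao"]
P_GNA = _P["g_na"]; P_GCAL = _P["g_cal"]; P_GTO = _P["g_to"]
P_GKR = _P["g_kr"]; P_GKS = _P["g_ks"]; P_GK1 = _P["g_k1"]; P_GF = _P["g_f"]
P_GBNA = _P["g_bna"]; P_GBCA = _P["g_bca"]; P_GPCA = _P["g_pca"]
P_PNAK = _P["p_nak"]; P_KNCX = _P["k_ncx"]
P_NASH = _P["na_avail_shift"]; P_NATH = _P["na_tauh_scale"]; P_NATJ = _P["na_tauj_scale"]
P_KFCA = _P["kfca"]; P_DCA = _P["d_ca"]
P_SVMAX = _P["serca_vmax"]; P_SKM = _P["serca_km"]; P_SHILL = _P["serca_hill"]
P_SLEAK = _P["serca_kleak"]
P_RNU = _P["ryr_nu"]; P_RSC = _P["ryr_scale_c"]; P_RS2 = _P["ryr_scale_p2"]
P_RS4 = _P["ryr_scale_p4"]
P_RKAMIN = _P["ryr_ka_min"]; P_RKAMAX = _P["ryr_ka_max"]
P_RKASR = _P["ryr_kasr"]; P_RHSR = _P["ryr_hsr"]; P_RHA = _P["ryr_ha"]
P_RTAUA = _P["ryr_tau_act"]; P_RKW = _P["ryr_kw"]
P_RTAUI = _P["ryr_tau_inact"]; P_RTAUR = _P["ryr_tau_rec"]
P_RKLUM = _P["ryr_klum"]
P_RWHYST = _P["ryr_whyst"]
P_RCAREST = _P["ryr_carest"]
P_IPNU = _P["ip3_nu"]; P_IPPO = _P["ip3_po"]
P_B1T = _P["buf1_tot"]; P_B1ON = _P["buf1_kon"]; P_B1OFF = _P["buf1_koff"]
P_B2T = _P["buf2_tot"]; P_B2ON = _P["buf2_kon"]; P_B2OFF = _P["buf2_koff"]
P_BFT = _P["fluo_tot"]; P_BFON = _P["fluo_kon"]; P_BFOFF = _P["fluo_koff"]
P_CSQT = _P["csq_tot"]; P_CSQKD = _P["csq_kd"]
P_IFNA = _P["if_na_frac"]; P_STIMK = _P["stim_k_assign"]

# state layout (fixed part)
IV = 0
IM, IH, IJ = 1, 2, 3
ID, IF1, IF2, IFCA = 4, 5, 6, 7
IR, IS = 8, 9
IXR1, IXR2 = 10, 11
IXS = 12
IXF = 13
INAI, IKI = 14, 15
ICASR = 16
NFIXED = 17  # then per shell: RyR activation a, armed flag w, state timer,
             # free Ca, bound buffer 1, bound buffer 2, bound Fluo-4


def nstate(n_shells: int) -> int:
    return NFIXED + 7 * n_shells


# drive vector layout (piecewise-constant protocol inputs)
D_STIM = 0     # stimulus current, pA/pF (negative = depolarizing)
D_CLAMP = 1    # >0.5: voltage clamp (dV/dt = 0)
D_VCLAMP = 2   # clamp potential (informational; state V is set by caller)
D_ICALF = 3    # >0.5: L-type channel forced open, i_cal = 0.5*(V - E_Ca)
D_FORCE_C = 4  # RyR open-probability override per site; < 0 means no override
D_FORCE_P2 = 5
D_FORCE_P4 = 6
D_BIAS = 7     # holding bias current, pA/pF
D_FORCE_ALL = 8  # open-probability override applied to every shell (< 0: none)
NDRIVE = 9

# recorded-current layout
C_NA, C_NAB, C_CAL, C_CAB, C_TO, C_KR, C_KS, C_K1, C_F, C_NCX, C_NAK, C_PCA, \
    C_STIM, C_TOT = range(14)
C_JRELC, C_JRELP2, C_JRELP4, C_JSERCA, C_JIP3, C_JLEAK, C_JCAMEM, \
    C_JRELTOT = range(14, 22)
NCUR = 22

CUR_NAMES = (
    "i_na", "i_nab", "i_cal", "i_cab", "i_to", "i_kr", "i_ks", "i_k1", "i_f",
    "i_ncx", "i_nak", "i_pca", "i_stim", "i_tot",
    "j_rel_c", "j_rel_p2", "j_rel_p4", "j_serca", "j_ip3", "j_leak", "j_ca_mem",
    "j_rel_total",
)


@njit(cache=True)
def _ryr_act(ca_loc, casr, p):
    """Steady-state activation of one release site.

    A sharp logistic threshold on local cytosolic Ca; the midpoint ka falls
    as the SR loads (luminal sensitization), so a filling store makes the
    site progressively easier to trigger -- the basis of both CICR and the
    spontaneous calcium clock.
    """
    s_sr = 1.0 / (1.0 + (p[P_RKASR] / casr) ** p[P_RHSR])
    ka = p[P_RKAMAX] - (p[P_RKAMAX] - p[P_RKAMIN]) * s_sr
    z = (ca_loc - ka) * p[P_RHA] / ka
    if z > 35.0:
        return 1.0
    if z < -35.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-z))


@njit(cache=True)
def rhs(y, p, centers, vols, areas, dr, s2, s4, cidx, drive, dy, xinf, xtau, cur):
    n = centers.size
    for i in range(y.size):
        dy[i] = 0.0
        xinf[i] = 0.0
        xtau[i] = 0.0
    for i in range(NCUR):
        cur[i] = 0.0

    v = y[IV]
    nai = y[INAI]
    ki = y[IKI]
    casr = y[ICASR]
    ca_sl = y[NFIXED + 4 * n - 1]  # outermost shell free Ca

    nao = p[P_NAO]; ko = p[P_KO]; cao = p[P_CAO]
    ena = RTF * math.log(nao / nai)
    ek = RTF * math.log(ko / ki)
    eks = RTF * math.log((ko + 0.03 * nao) / (ki + 0.03 * nai))
    eca = 0.5 * RTF * math.log(cao / ca_sl)

    # ---------------- I_Na (m^3 h j) -----------------------------------
    m_inf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0))
    tau_m = am * bm
    va = v + p[P_NASH]  # availability shift (Brugada: +6.7 -> leftward curves)
    h_inf = 1.0 / (1.0 + math.exp((va + 71.55) / 7.43)) ** 2
    if va < -40.0:
        ah = 0.057 * math.exp(-(va + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * va) + 310000.0 * math.exp(0.3485 * va)
        tau_h = 1.0 / (ah + bh) * p[P_NATH]
    else:
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(va + 10.66) / 11.1)))
        tau_h = 1.0 / bh
    j_inf = h_inf
    if va < -40.0:
        aj = ((-25428.0 * math.exp(0.2444 * va) - 6.948e-6 * math.exp(-0.04391 * va))
              * (va + 37.78)) / (1.0 + math.exp(0.311 * (va + 79.23)))
        bj = 0.02424 * math.exp(-0.01052 * va) / (1.0 + math.exp(-0.1378 * (va + 40.14)))
        tau_j = 1.0 / (aj + bj) * p[P_NATJ]
    else:
        bj = 0.6 * math.exp(0.057 * va) / (1.0 + math.exp(-0.1 * (va + 32.0)))
        tau_j = 1.0 / bj
    xinf[IM] = m_inf; xtau[IM] = tau_m
    xinf[IH] = h_inf; xtau[IH] = tau_h
    xinf[IJ] = j_inf; xtau[IJ] = tau_j
    i_na = p[P_GNA] * y[IM] ** 3 * y[IH] * y[IJ] * (v - ena)

    # ---------------- I_CaL (d f1 f2 fCa, ohmic E_app = +60 mV) --------
    d_inf = 1.0 / (1.0 + math.exp(-(v + 9.1) / 6.0))
    tau_d = 0.6 + 2.4 * math.exp(-((v + 9.1) / 30.0) ** 2)
    f_inf = 1.0 / (1.0 + math.exp((v + 27.4) / 7.1))
    tau_f1 = 10.0 + 150.0 * math.exp(-((v + 25.0) / 20.0) ** 2)
    tau_f2 = 250.0 + 900.0 * math.exp(-((v + 30.0) / 40.0) ** 2)
    fca_inf = 1.0 / (1.0 + (ca_sl / p[P_KFCA]) ** 2)
    xinf[ID] = d_inf; xtau[ID] = tau_d
    xinf[IF1] = f_inf; xtau[IF1] = tau_f1
    xinf[IF2] = f_inf; xtau[IF2] = tau_f2
    xinf[IFCA] = fca_inf; xtau[IFCA] = 8.0
    if drive[D_ICALF] > 0.5:
        i_cal = 0.5 * (v - eca)  # pipette Ca-puff surrogate: channel held open
    else:
        i_cal = p[P_GCAL] * y[ID] * y[IF1] * y[IF2] * y[IFCA] * (v - 60.0)

    # ---------------- I_to ---------------------------------------------
    r_inf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    tau_r = 9.5 * math.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    s_inf = 1.0 / (1.0 + math.exp((v + 43.0) / 5.0))
    tau_s = 85.0 * math.exp(-((v + 45.0) ** 2) / 320.0) + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0)) + 3.0
    xinf[IR] = r_inf; xtau[IR] = tau_r
    xinf[IS] = s_inf; xtau[IS] = tau_s
    i_to = p[P_GTO] * y[IR] * y[IS] * (v - ek)

    # ---------------- I_Kr ---------------------------------------------
    xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    xr2_inf = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    xinf[IXR1] = xr1_inf; xtau[IXR1] = axr1 * bxr1
    xinf[IXR2] = xr2_inf; xtau[IXR2] = axr2 * bxr2
    i_kr = p[P_GKR] * math.sqrt(ko / 5.4) * y[IXR1] * y[IXR2] * (v - ek)

    # ---------------- I_Ks ---------------------------------------------
    xs_inf = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    axs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((v - 60.0) / 20.0))
    xinf[IXS] = xs_inf; xtau[IXS] = axs * bxs
    i_ks = p[P_GKS] * y[IXS] ** 2 * (v - eks)

    # ---------------- I_K1 (instantaneous rectifier) --------------------
    vk = v - ek
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (vk - 200.0)))
    bk1 = (3.0 * math.exp(0.0002 * (vk + 100.0)) + math.exp(0.1 * (vk - 10.0))) / (
        1.0 + math.exp(-0.5 * vk))
    xk1 = ak1 / (ak1 + bk1)
    i_k1 = p[P_GK1] * math.sqrt(ko / 5.4) * xk1 * vk

    # ---------------- I_f ------------------------------------------------
    xf_inf = 1.0 / (1.0 + math.exp((v + 78.0) / 5.0))
    tau_xf = 15.0 + 950.0 / (1.0 + math.exp((v + 15.0) / 10.0))
    xinf[IXF] = xf_inf; xtau[IXF] = tau_xf
    i_fna = p[P_IFNA] * p[P_GF] * y[IXF] * (v - ena)
    i_fk = (1.0 - p[P_IFNA]) * p[P_GF] * y[IXF] * (v - ek)
    i_f = i_fna + i_fk

    # ---------------- pumps & exchangers --------------------------------
    i_nak = (p[P_PNAK] * (ko / (ko + 1.0)) * (nai / (nai + 40.0))
             / (1.0 + 0.1245 * math.exp(-0.1 * v / RTF) + 0.0353 * math.exp(-v / RTF)))
    ef = math.exp(0.35 * v / RTF)
    er = math.exp(-0.65 * v / RTF)
    i_ncx = (p[P_KNCX] * (ef * nai ** 3 * cao - er * nao ** 3 * ca_sl)
             / ((87.5 ** 3 + nao ** 3) * (1.38 + cao) * (1.0 + 0.1 * er)))
    i_pca = p[P_GPCA] * ca_sl / (ca_sl + 0.0005)
    i_bna = p[P_GBNA] * (v - ena)
    i_bca = p[P_GBCA] * (v - eca)

    i_stim = drive[D_STIM] + drive[D_BIAS]
    i_tot = (i_na + i_bna + i_cal + i_bca + i_to + i_kr + i_ks + i_k1 + i_f
             + i_ncx + i_nak + i_pca)

    if drive[D_CLAMP] > 0.5:
        dy[IV] = 0.0
    else:
        dy[IV] = -(i_tot + i_stim)

    # ---------------- intracellular Na+/K+ ------------------------------
    vtot = 0.0
    for i in range(n):
        vtot += vols[i]
    vcyt = p[P_VCYT] * vtot
    vsr = p[P_VSR] * vtot
    kconv = p[P_CM] * 1000.0 / (FARADAY * vcyt)
    dy[INAI] = -(i_na + i_bna + i_fna + 3.0 * i_nak + 3.0 * i_ncx) * kconv
    dy[IKI] = -(i_to + i_kr + i_ks + i_k1 + i_fk - 2.0 * i_nak
                + i_stim * p[P_STIMK]) * kconv

    # ---------------- calcium subsystem ---------------------------------
    a0 = NFIXED
    w0 = NFIXED + n
    t0_ = NFIXED + 2 * n
    ca0 = NFIXED + 3 * n
    b1_0 = NFIXED + 4 * n
    b2_0 = NFIXED + 5 * n
    bf_0 = NFIXED + 6 * n

    # radial diffusion (finite volume, zero-flux at both boundaries;
    # sarcolemmal exchange is added separately to the outermost shell)
    for i in range(n - 1):
        flx = p[P_DCA] * areas[i + 1] * (y[ca0 + i + 1] - y[ca0 + i]) / dr
        dy[ca0 + i] += flx / (p[P_VCYT] * vols[i])
        dy[ca0 + i + 1] -= flx / (p[P_VCYT] * vols[i + 1])

    # buffering (explicit mass-action kinetics)
    for i in range(n):
        cai = y[ca0 + i]
        r1 = p[P_B1ON] * cai * (p[P_B1T] - y[b1_0 + i]) - p[P_B1OFF] * y[b1_0 + i]
        r2 = p[P_B2ON] * cai * (p[P_B2T] - y[b2_0 + i]) - p[P_B2OFF] * y[b2_0 + i]
        rf = p[P_BFON] * cai * (p[P_BFT] - y[bf_0 + i]) - p[P_BFOFF] * y[bf_0 + i]
        dy[b1_0 + i] = r1
        dy[b2_0 + i] = r2
        dy[bf_0 + i] = rf
        dy[ca0 + i] -= r1 + r2 + rf

    # SERCA uptake (distributed) and SR leak
    sr_net = 0.0  # mM um^3 / ms gained by the SR
    jup_tot = 0.0
    jleak_tot = 0.0
    hh = p[P_SHILL]
    for i in range(n):
        cai = y[ca0 + i]
        occ = cai ** hh / (cai ** hh + p[P_SKM] ** hh)
        jup = p[P_SVMAX] * occ
        jleak = p[P_SLEAK] * (casr - cai)
        dy[ca0 + i] += jleak - jup
        va = p[P_VCYT] * vols[i]
        sr_net += (jup - jleak) * va
        jup_tot += jup * va
        jleak_tot += jleak * va

    # RyR release: relays distributed over every shell ("fire-diffuse-fire").
    # Each shell carries an activation gate a_i (sharp Ca threshold with
    # luminal sensitization) and a binary armed flag w_i managed by the
    # stepper.  Density is uniform except for the named release locations
    # (central SR region, 2 um and 4 um sites), which carry their own
    # multipliers.  The outermost relay sits in the sub-sarcolemmal shell,
    # so the L-type Ca spike triggers it directly (junctional coupling).
    s_lum = casr * casr / (casr * casr + p[P_RKLUM] * p[P_RKLUM])
    ncen = cidx.size
    jrel_c = 0.0
    jrel_tot = 0.0
    jip3_tot = 0.0
    j2 = 0.0
    j4 = 0.0
    force_all = drive[D_FORCE_ALL]
    # relays populate shells from the center up to ~1 um below the
    # sarcolemma (the sub-membrane shells have no junctional SR of their
    # own); the shallowest relay senses sub-membrane Ca directly, so the
    # L-type trigger reaches it without a diffusion delay
    n_rel = n - 1
    for i in range(n):
        cai = y[ca0 + i]
        if i == n_rel - 1 and ca_sl > cai:
            cai_trig = ca_sl
        else:
            cai_trig = cai
        xinf[a0 + i] = _ryr_act(cai_trig, casr, p)
        xtau[a0 + i] = p[P_RTAUA]
        po = y[a0 + i] * y[w0 + i]
        dens = 1.0 if i < n_rel else 0.0
        central = i <= cidx[ncen - 1]
        if central:
            dens *= p[P_RSC]
            if drive[D_FORCE_C] >= 0.0:
                po = drive[D_FORCE_C]
        if i == s2:
            dens *= p[P_RS2]
        if i == s4:
            dens *= p[P_RS4]
        # forced-opening overrides span the site's ~1.5 um neighbourhood
        if drive[D_FORCE_P2] >= 0.0 and abs(i - s2) <= 1:
            po = drive[D_FORCE_P2]
        if drive[D_FORCE_P4] >= 0.0 and abs(i - s4) <= 1:
            po = drive[D_FORCE_P4]
        if force_all >= 0.0:
            po = force_all
        j = p[P_RNU] * dens * po * s_lum * (casr - cai)
        jip = 0.0
        if central:
            jip = p[P_IPNU] * p[P_IPPO] * (casr - cai)
        dy[ca0 + i] += j + jip
        va = p[P_VCYT] * vols[i]
        sr_net -= (j + jip) * va
        jrel_tot += j * va
        jip3_tot += jip * va
        if central:
            jrel_c += j * va
        if i == s2:
            j2 = j * va
        if i == s4:
            j4 = j * va

    # SR free Ca with rapid calsequestrin buffering
    beta = 1.0 / (1.0 + p[P_CSQT] * p[P_CSQKD] / (p[P_CSQKD] + casr) ** 2)
    dy[ICASR] = beta * sr_net / vsr

    # trans-sarcolemmal Ca flux into the outermost shell
    va_out = p[P_VCYT] * vols[n - 1]
    kca = p[P_CM] * 1000.0 / (2.0 * FARADAY * va_out)
    jmem = -(i_cal + i_bca + i_pca) * kca + i_ncx * 2.0 * kca
    dy[ca0 + n - 1] += jmem

    # ---------------- record currents/fluxes ----------------------------
    cur[C_NA] = i_na; cur[C_NAB] = i_bna; cur[C_CAL] = i_cal; cur[C_CAB] = i_bca
    cur[C_TO] = i_to; cur[C_KR] = i_kr; cur[C_KS] = i_ks; cur[C_K1] = i_k1
    cur[C_F] = i_f; cur[C_NCX] = i_ncx; cur[C_NAK] = i_nak; cur[C_PCA] = i_pca
    cur[C_STIM] = i_stim; cur[C_TOT] = i_tot
    cur[C_JRELC] = jrel_c / vcyt
    cur[C_JRELP2] = j2 / vcyt
    cur[C_JRELP4] = j4 / vcyt
    cur[C_JSERCA] = jup_tot / vcyt
    cur[C_JIP3] = jip3_tot / vcyt
    cur[C_JLEAK] = jleak_tot / vcyt
    cur[C_JCAMEM] = jmem * va_out / vcyt
    cur[C_JRELTOT] = jrel_tot / vcyt
    return 0


@njit(cache=True)
def integrate(y, t0, t1, p, centers, vols, areas, dr, s2, s4, cidx, drive,
              dt_min, dt_max, rec, out_y, out_c):
    """March ``y`` from t0 to t1 under piecewise-constant ``drive``.

    Records state+currents at the times in ``rec`` (must be ascending and in
    [t0, t1]).  Returns (t_reached, n_steps); n_steps < 0 flags a non-finite
    state (integration fault).
    """
    n = centers.size
    ns = y.size
    dy = np.zeros(ns)
    xinf = np.zeros(ns)
    xtau = np.zeros(ns)
    cur = np.zeros(NCUR)
    a0 = NFIXED
    w0 = NFIXED + n
    t0_ = NFIXED + 2 * n
    ca0 = NFIXED + 3 * n
    b1_0 = NFIXED + 4 * n
    b2_0 = NFIXED + 5 * n
    bf_0 = NFIXED + 6 * n

    t = t0
    k = 0
    nst = 0
    while k < rec.size and rec[k] <= t0 + 1e-9:
        rhs(y, p, centers, vols, areas, dr, s2, s4, cidx, drive, dy, xinf, xtau, cur)
        for q in range(ns):
            out_y[k, q] = y[q]
        for q in range(NCUR):
            out_c[k, q] = cur[q]
        k += 1

    while t < t1 - 1e-9:
        rhs(y, p, centers, vols, areas, dr, s2, s4, cidx, drive, dy, xinf, xtau, cur)
        if not math.isfinite(dy[IV]) or not math.isfinite(y[IV]):
            return t, -nst - 1
        rmax = 0.0
        for i in range(n):
            rr = abs(dy[ca0 + i]) / (y[ca0 + i] + 2e-4)
            if rr > rmax:
                rmax = rr
        dt = dt_max / (1.0 + 4.0 * abs(dy[IV]) + 50.0 * rmax)
        if dt < dt_min:
            dt = dt_min
        tn = t1
        if k < rec.size and rec[k] < tn:
            tn = rec[k]
        if t + dt > tn - 1e-12:
            dt = tn - t
        for q in range(ns):
            if xtau[q] > 0.0:
                y[q] = xinf[q] + (y[q] - xinf[q]) * math.exp(-dt / xtau[q])
            else:
                y[q] += dt * dy[q]
        for i in range(n):
            if y[ca0 + i] < 1e-9:
                y[ca0 + i] = 1e-9
            if y[b1_0 + i] < 0.0:
                y[b1_0 + i] = 0.0
            elif y[b1_0 + i] > p[P_B1T]:
                y[b1_0 + i] = p[P_B1T]
            if y[b2_0 + i] < 0.0:
                y[b2_0 + i] = 0.0
            elif y[b2_0 + i] > p[P_B2T]:
                y[b2_0 + i] = p[P_B2T]
            if y[bf_0 + i] < 0.0:
                y[bf_0 + i] = 0.0
            elif y[bf_0 + i] > p[P_BFT]:
                y[bf_0 + i] = p[P_BFT]
        if y[ICASR] < 1e-9:
            y[ICASR] = 1e-9
        # per-shell release state machine: armed (w = 1) vs refractory (0).
        # An armed relay shuts when the SR is drawn down below whyst*kw or
        # after ryr_tau_inact ms of continuous opening; re-arming requires
        # tau_rec ms of refractoriness, a store refilled past kw, and
        # diastolic local Ca.  Discrete hysteresis in time: no marginal
        # steady leak state exists.
        casr_now = y[ICASR]
        sr_low = casr_now < p[P_RKW] * p[P_RWHYST]
        sr_ok = casr_now > p[P_RKW]
        for i in range(n):
            iw = w0 + i
            ia = a0 + i
            it = t0_ + i
            if y[iw] >= 0.5:
                if y[ia] > 0.5:
                    y[it] += dt
                else:
                    y[it] = 0.0
                if sr_low or y[it] > p[P_RTAUI]:
                    y[iw] = 0.0
                    y[it] = 0.0
            else:
                y[it] += dt
                if (y[it] >= p[P_RTAUR] and sr_ok
                        and y[ca0 + i] < p[P_RCAREST]):
                    y[iw] = 1.0
                    y[it] = 0.0
        t += dt
        nst += 1
        if k < rec.size and t >= rec[k] - 1e-9:
            rhs(y, p, centers, vols, areas, dr, s2, s4, cidx, drive, dy, xinf, xtau, cur)
            for q in range(ns):
                out_y[k, q] = y[q]
            for q in range(NCUR):
                out_c[k, q] = cur[q]
            k += 1
    return t, nst
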