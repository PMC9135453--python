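"""Passive-limit detailed-balance experiment shared by the acceptance tests.

Two fixed parallel filaments; a population of independent crosslinkers with
one head permanently anchored at the midpoint of the first filament and the
other head hopping S ⇌ D on the second via the package's binding-density and
off-rate machinery (vm = 0).  Because the geometry is static, the S→D
density is computed once and the chain is advanced with exact per-step
Bernoulli draws; occupancy across binding sites must follow exp(−βE(ℓf(s)))
for every energy-partition factor λ.
"""

import numpy as np
from scipy.stats import chi2

import cytorod as ct
from cytorod.geometry import KBT_ROOM
from cytorod.kinetics import MotorParams, rate_D_to_S, rate_S_to_D
from cytorod.scenarios import quat_from_director


def run_passive_chain(lam, seed=0, target_events=1_000_000, h=5e-5, n_motors=2500,
                      kappa=6.0, ko_d=30.0, offset=0.077, max_steps=4_000_000):
    """Returns a dict with occupancy/visit/unbind histograms and the χ² of the
    occupancy against the Boltzmann expectation."""
    fs = ct.FilamentSet.from_list(
        [
            ct.Spherocylinder(0, [0, 0, 0], quat_from_director([1.0, 0, 0]),
                              0.1, 0.025, mobile=False, bindable=False),
            ct.Spherocylinder(1, [0.0, offset, 0.0], quat_from_director([1.0, 0, 0]),
                              0.20, 0.025, mobile=False),
        ]
    )
    p = MotorParams(kappa=kappa, ell0=0.05, vm=0.0, ko_s=1.0, ko_d=ko_d,
                    ka=1e-3, ke=0.01, lam=lam, eps=400.0)
    dens = rate_S_to_D(np.zeros(3), 0, 0.0125, fs, p, ct.Boundary())
    cum = np.cumsum(dens.w)
    cum /= cum[-1]
    radsum = 0.025

    def ellf_of(s):
        return np.maximum(np.sqrt(offset**2 + s**2) - radsum, 0.0)

    rng = np.random.default_rng(seed)
    edges = np.linspace(-0.10, 0.10, 31)
    nbin = len(edges) - 1
    bound = np.zeros(n_motors, dtype=bool)
    site_bin = np.zeros(n_motors, dtype=np.int64)
    site_q = np.zeros(n_motors)   # cached per-step unbinding probability
    occ = np.zeros(nbin)
    visit = np.zeros(nbin)
    unbind = np.zeros(nbin)
    p_on = -np.expm1(-dens.rate * h)
    events = 0
    steps = 0
    while events < target_events and steps < max_steps:
        steps += 1
        b = np.nonzero(bound)[0]
        if len(b):
            fire = rng.random(len(b)) < site_q[b]
            ub = b[fire]
            if len(ub):
                unbind += np.bincount(site_bin[ub], minlength=nbin)
                events += len(ub)
                bound[ub] = False
        u = np.nonzero(~bound)[0]
        if len(u):
            fire = rng.random(len(u)) < p_on
            nb = u[fire]
            if len(nb):
                k = np.minimum(np.searchsorted(cum, rng.random(len(nb))), len(dens.w) - 1)
                s_new = dens.s[k] + (rng.random(len(nb)) - 0.5) * dens.ds[k]
                site_bin[nb] = np.clip(
                    np.searchsorted(edges, s_new, side="right") - 1, 0, nbin - 1
                )
                site_q[nb] = -np.expm1(-rate_D_to_S(ellf_of(s_new), p) * h)
                bound[nb] = True
                visit += np.bincount(site_bin[nb], minlength=nbin)
        if steps % 2 == 0:
            occ += np.bincount(site_bin[bound], minlength=nbin)

    # Boltzmann expectation over each bin (fine quadrature, h→0 limit)
    sg = np.linspace(edges[0], edges[-1], 100001)
    energy = 0.5 * kappa * (ellf_of(sg) - p.ell0) ** 2
    boltz = np.exp(-energy / KBT_ROOM)
    idx = np.clip(np.searchsorted(edges, sg, side="right") - 1, 0, nbin - 1)
    expect = np.bincount(idx, weights=boltz, minlength=nbin)
    expect *= occ.sum() / expect.sum()
    # compound variance: N_b visits, each a geometric dwell with parameter q̄_b
    q_dens = -np.expm1(-rate_D_to_S(ellf_of(sg), p) * h)
    rho_on = np.exp(-(1 - lam) * energy / KBT_ROOM)
    qbar = np.bincount(idx, weights=q_dens * rho_on, minlength=nbin) / np.bincount(
        idx, weights=rho_on, minlength=nbin
    )
    var = visit * (1 - qbar) / qbar**2 + visit / qbar**2
    var *= 0.25  # occupancy accumulated every 2nd step
    stat = float(np.sum((occ - expect) ** 2 / np.maximum(var, 1e-300)))
    dof = nbin - 1
    return {
        "events": events,
        "chi2": stat,
        "dof": dof,
        "p_value": float(chi2.sf(stat, dof)),
        "occ": occ,
        "expect": expect,
        "visit": visit,
        "unbind": unbind,
    }
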