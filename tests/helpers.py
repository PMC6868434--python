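"""Independent brute-force hydrogen-bond oracle used to cross-check the
detectors: a plain all-pairs scan over donor x acceptor atoms that
re-applies every criterion with its own arithmetic (no detector code)."""

from __future__ import annotations

import numpy as np

from hbstrand.hbond_detect import DetectorParams, prepare_sites


def _ang(a, b, c):
    u = a - b
    v = c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))


def _acceptor_plane_normal(acc):
    ante = acc.antecedent
    if ante is None:
        return None
    ref = None
    for at in acc.residue.atoms:
        if at.name in (acc.atom.name, ante.name):
            continue
        if np.linalg.norm(at.pos - ante.pos) < 1.8:
            ref = at
            break
    if ref is None:
        return None
    n = np.cross(acc.atom.pos - ante.pos, ref.pos - ante.pos)
    norm = np.linalg.norm(n)
    return n / norm if norm > 1e-6 else None


def oracle_bond_keys(unit, method: str, params: DetectorParams | None = None) -> set:
    """Set of (donor residue key, donor atom, acceptor residue key,
    acceptor atom) accepted by a straightforward re-application of the
    criteria over every cross-interface donor/acceptor pair."""
    params = params or DetectorParams(method=method)
    prot_don, dna_don, prot_acc, dna_acc = prepare_sites(unit)
    keys = set()
    for donors, acceptors in ((prot_don, dna_acc), (dna_don, prot_acc)):
        for ds in donors:
            for acc in acceptors:
                d_da = np.linalg.norm(ds.atom.pos - acc.atom.pos)
                if d_da < 0.5:
                    continue
                accepted = False
                for h in ds.h_positions:
                    theta = _ang(ds.atom.pos, h, acc.atom.pos)
                    if method == "geometric":
                        if d_da > params.max_da:
                            continue
                        if np.linalg.norm(h - acc.atom.pos) > params.max_ha:
                            continue
                        if theta < params.min_dha_deg:
                            continue
                        if acc.antecedent is not None:
                            if _ang(h, acc.atom.pos, acc.antecedent.pos) < params.min_haaa_deg:
                                continue
                        accepted = True
                    else:
                        if d_da > params.energy_prescreen_da or theta < 90.0:
                            continue
                        phi = 180.0
                        if acc.antecedent is not None:
                            phi = _ang(h, acc.atom.pos, acc.antecedent.pos)
                        gamma = 0.0
                        if acc.hybridization == "sp2":
                            n = _acceptor_plane_normal(acc)
                            if n is not None:
                                v = acc.atom.pos - h
                                s = abs(np.dot(v / np.linalg.norm(v), n))
                                gamma = np.degrees(np.arcsin(min(1.0, s)))
                        ct2 = np.cos(np.radians(theta)) ** 2
                        dh, ah = ds.hybridization, acc.hybridization
                        if dh == "sp3" and ah == "sp3":
                            f = ct2 * np.cos(np.radians(phi - 109.5)) ** 2
                        elif dh == "sp3" and ah == "sp2":
                            f = ct2 * np.cos(np.radians(phi)) ** 2
                        elif dh == "sp2" and ah == "sp3":
                            f = ct2 * ct2
                        else:
                            f = ct2 * np.cos(np.radians(max(phi, gamma))) ** 2
                        r = params.d0 / d_da
                        e = params.v0 * (5.0 * r**12 - 6.0 * r**10) * f
                        if e <= params.energy_cutoff:
                            accepted = True
                    if accepted:
                        break
                if accepted:
                    keys.add((ds.residue.key, ds.atom.name, acc.residue.key, acc.atom.name))
    return keys


def detected_bond_keys(bonds) -> set:
    return {
        (hb.donor_res.key, hb.donor_atom.name, hb.acceptor_res.key, hb.acceptor_atom.name)
        for hb in bonds
    }
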