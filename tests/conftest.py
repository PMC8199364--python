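import numpy as np
import pytest

from helixmd.builder import build_bundle, build_chain


@pytest.fixture(scope="session")
def ideal_helix():
    """20-residue chain built at the ideal alpha-helix torsions (-60, -50)."""
    return build_chain(["ALA"] * 20, [(-60.0, -50.0)] * 20)


@pytest.fixture(scope="session")
def wtrop_bundle():
    """Hairpin dimer: 2 chains x 63 residues with HELIX1-LOOP-HELIX2 layout."""
    return build_bundle("wtrop_like")


@pytest.fixture(scope="session")
def rm6_bundle():
    """Four-helix tetramer: 4 chains x 58 residues, one helix per chain."""
    return build_bundle("rm6_like")


def ca_coords(system, chain_id="A", res_range=None):
    """Ordered CA coordinates of one chain (test helper)."""
    out = []
    for (cid, r, _n) in system.residues(chain_id):
        if res_range is not None and not (res_range[0] <= r <= res_range[1]):
            continue
        out.append(system.atoms[system.index_of(cid, r, "CA")].position)
    return np.array(out)


def parametric_helix(n, radius=0.23, pitch=0.54, res_per_turn=3.6):
    """Closed-form ideal helix wound about z: the independent geometry oracle.

    Rise per residue = pitch / res_per_turn; twist = 360 / res_per_turn deg.
    """
    k = np.arange(n)
    ang = 2.0 * np.pi * k / res_per_turn
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            pitch * k / res_per_turn])


def dihedral_plane_normal(p0, p1, p2, p3):
    """Brute-force dihedral via explicit plane normals (independent oracle)."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


def brute_force_hbonds(system, coords, max_dist=0.35, max_angle=30.0):
    """Enumerate every donor-acceptor pair by direct geometry (oracle).

    Donors: backbone N (amide H by planar reconstruction) and water O-H.
    Acceptors: backbone carbonyl O and water O. Applies the same <=2-bond
    chemical exclusion as the implementation. Returns a set of
    (donor_key, acceptor_key) pairs.
    """
    donors = []  # (key, n_pos, h_positions, chain, res, kind)
    acceptors = []  # (key, pos, chain, res, kind)
    for (cid, r, name) in system.residues():
        water = name in ("HOH", "SOL")
        if water:
            oname = "OW" if system.has_atom(cid, r, "OW") else "O"
            o = system.atoms[system.index_of(cid, r, oname)].position
            o = coords[system.index_of(cid, r, oname)]
            acceptors.append(((cid, r, oname), o, cid, r, "W"))
            hs = [coords[system.index_of(cid, r, h)]
                  for h in ("HW1", "HW2") if system.has_atom(cid, r, h)]
            if hs:
                donors.append(((cid, r, oname), o, hs, cid, r, "W"))
            continue
        if system.has_atom(cid, r, "O"):
            acceptors.append(((cid, r, "O"), coords[system.index_of(cid, r, "O")],
                              cid, r, "P"))
        if name != "PRO" and system.has_atom(cid, r, "N") \
                and system.has_atom(cid, r - 1, "C") and system.has_atom(cid, r, "CA"):
            npos = coords[system.index_of(cid, r, "N")]
            cprev = coords[system.index_of(cid, r - 1, "C")]
            ca = coords[system.index_of(cid, r, "CA")]
            u = (cprev - npos) / np.linalg.norm(cprev - npos)
            v = (ca - npos) / np.linalg.norm(ca - npos)
            hdir = -(u + v)
            hdir /= np.linalg.norm(hdir)
            donors.append(((cid, r, "N"), npos, [npos + 0.1 * hdir], cid, r, "P"))
    pairs = set()
    for (dkey, dpos, hs, dc, dr, dk) in donors:
        for (akey, apos, ac, ar, ak) in acceptors:
            if dc == ac and dr == ar:
                continue
            if dk == "P" and ak == "P" and dc == ac and dr - ar == 1:
                continue
            da = apos - dpos
            dist = np.linalg.norm(da)
            if dist > max_dist or dist < 1e-9:
                continue
            for h in hs:
                hd = (h - dpos) / np.linalg.norm(h - dpos)
                ang = np.degrees(np.arccos(np.clip(np.dot(hd, da / dist), -1, 1)))
                if ang <= max_angle:
                    pairs.add((dkey, akey))
                    break
    return pairs
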