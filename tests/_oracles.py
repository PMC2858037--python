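"""Independent brute-force oracles for the test suite.

Everything here is coded from scratch (plain Python, no imports from the
package's computational internals) so that agreement between the package and
these oracles is a meaningful check: the NN parameter set is hard-coded
literally, alignments are enumerated naively, candidate enumeration scans
every (start, length, strand) triple, and PSC search enumerates the full
cartesian product.
"""

from __future__ import annotations

import itertools
import math

# --- nearest-neighbor parameters, written out literally -----------------------
# (dH kcal/mol, dS cal/(mol K)) per top-strand dinucleotide, unified WC set.
NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}
SYM = (0.0, -1.4)
COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
R_GAS = 1.987


def dg37(dh: float, ds: float) -> float:
    return dh - 310.15 * ds / 1000.0


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def selfcomp_seq(seq: str) -> bool:
    return len(seq) % 2 == 0 and seq == rc(seq)


# --- duplex free energy --------------------------------------------------------

def alignment_dg(p1: str, p2: str, offset: int) -> float:
    """dG37 of the ungapped annealing alignment: p1 5'->3' over p2 3'->5'.

    Column i of p1 pairs base p2[len(p2) - 1 - (i - offset)]; consecutive
    complementary columns stack; initiation applies at the first and last
    matched pair; the symmetry term applies when the strands are identical.
    """
    matched = []
    for i in range(len(p1)):
        j = i - offset
        if 0 <= j < len(p2) and COMP[p1[i]] == p2[len(p2) - 1 - j]:
            matched.append(i)
    if not matched:
        return 0.0
    total = 0.0
    for a, b in zip(matched, matched[1:]):
        if b == a + 1:
            dh, ds = NN[p1[a : a + 2]]
            total += dg37(dh, ds)
    for col in (matched[0], matched[-1]):
        dh, ds = INIT[p1[col]]
        total += dg37(dh, ds)
    if p1 == p2:
        total += dg37(*SYM)
    return total


def dimer_dg(p1: str, p2: str) -> float:
    best = 0.0
    for offset in range(-(len(p2) - 1), len(p1)):
        best = min(best, alignment_dg(p1, p2, offset))
    return best


def perfect_dg(seq: str) -> float:
    total = 0.0
    for i in range(len(seq) - 1):
        dh, ds = NN[seq[i : i + 2]]
        total += dg37(dh, ds)
    for b in (seq[0], seq[-1]):
        dh, ds = INIT[b]
        total += dg37(dh, ds)
    if selfcomp_seq(seq):
        total += dg37(*SYM)
    return total


def end_dg(seq: str) -> float:
    return perfect_dg(seq[-5:])


# --- melting temperature -------------------------------------------------------

def tm(seq: str, ct: float = 50e-9, mono: float = 50e-3,
       div: float = 1.5e-3, dntp: float = 0.6e-3) -> float:
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = NN[seq[i : i + 2]]
        dh += h
        ds += s
    for b in (seq[0], seq[-1]):
        h, s = INIT[b]
        dh += h
        ds += s
    if selfcomp_seq(seq):
        dh += SYM[0]
        ds += SYM[1]
        x = 1.0
    else:
        x = 4.0
    na = (mono * 1e3 + 120.0 * math.sqrt(max(div - dntp, 0.0) * 1e3)) * 1e-3
    ds += 0.368 * (len(seq) - 1) * math.log(na)
    return 1000.0 * dh / (ds + R_GAS * math.log(ct / x)) - 273.15


# --- self-complementarity scoring ----------------------------------------------

def self_comp(seq: str):
    """(global, 3'-anchored) +1/-1 ungapped self-annealing scores, floored at 0."""
    L = len(seq)
    best_any = 0
    best_3p = 0
    for k in range(-(L - 1), L):
        score = 0
        covered_3p = False
        for i in range(L):
            j = L - 1 - i + k
            if 0 <= j < L:
                score += 1 if COMP[seq[i]] == seq[j] else -1
                if i == L - 1:
                    covered_3p = True
        best_any = max(best_any, score)
        if covered_3p:
            best_3p = max(best_3p, score)
    return float(best_any), float(best_3p)


# --- exhaustive candidate enumeration ------------------------------------------

def enumerate_primers(template: str, c, region=None, cond=None):
    """Every (strand, five_prime_start, length) window passing all filters.

    ``c`` is a DesignConstraints-like object; ``cond`` a ReactionConditions-like
    object (defaults match the package defaults).  Returns a dict keyed by
    (strand, start, length) -> property dict.
    """
    ct = cond.primer_concentration if cond else 50e-9
    mono = cond.monovalent if cond else 50e-3
    div = cond.divalent if cond else 1.5e-3
    dntp = cond.dntp if cond else 0.6e-3
    lo, hi = region if region else (0, len(template))
    out = {}
    for L in range(c.size_range[0], c.size_range[1] + 1):
        for s in range(lo, hi - L + 1):
            window = template[s : s + L]
            if any(b not in COMP for b in window):
                continue
            for strand in "+-":
                seq = window if strand == "+" else rc(window)
                t = tm(seq, ct, mono, div, dntp)
                gc = 100.0 * sum(b in "GC" for b in seq) / L
                e = end_dg(seq)
                sa, s3 = self_comp(seq)
                if not (c.tm_range[0] <= t <= c.tm_range[1]):
                    continue
                if not (c.gc_range[0] <= gc <= c.gc_range[1]):
                    continue
                if abs(e) > c.max_end_stability:
                    continue
                if sa > c.max_self_complementarity:
                    continue
                if s3 > c.max_3prime_self_complementarity:
                    continue
                start5 = s if strand == "+" else s + L - 1
                out[(strand, start5, L)] = {
                    "seq": seq, "tm": t, "gc": gc, "end_dg": e,
                    "self_any": sa, "self_3p": s3,
                }
    return out


def primer_pen(props, c) -> float:
    w = c.weights
    return (w.tm * abs(props["tm"] - c.tm_opt)
            + w.size * abs(len(props["seq"]) - c.size_opt)
            + w.gc * abs(props["gc"] - c.gc_opt)
            + w.self_comp * (props["self_any"] + props["self_3p"])
            + w.end_stability * abs(props["end_dg"]))


def top_pairs(template: str, c, region=None, cond=None, n=None):
    """Exhaustively paired + sorted candidate primer sets (fwd_key, rev_key, pen, size)."""
    prims = enumerate_primers(template, c, region, cond)
    fwd = {k: v for k, v in prims.items() if k[0] == "+"}
    rev = {k: v for k, v in prims.items() if k[0] == "-"}
    pairs = []
    for (_, f5, fl), fp in fwd.items():
        for (_, r5, rl), rp in rev.items():
            size = r5 - f5 + 1
            if not (c.product_size_range[0] <= size <= c.product_size_range[1]):
                continue
            if r5 - rl + 1 <= f5 + fl - 1:
                continue
            if abs(fp["tm"] - rp["tm"]) > c.max_tm_difference:
                continue
            pen = primer_pen(fp, c) + primer_pen(rp, c)
            pairs.append((pen, size, f5, fp["seq"], r5, ("+", f5, fl), ("-", r5, rl)))
    pairs.sort(key=lambda t: t[:5])
    if n is not None:
        pairs = pairs[:n]
    return pairs


# --- binding sites and amplicons -----------------------------------------------

def site_dg(primer: str, region: str) -> float:
    """dG37 of a primer laid along a same-length plus-strand region (match = pair)."""
    matched = [i for i in range(len(primer)) if primer[i] == region[i]]
    if not matched:
        return 0.0
    total = 0.0
    for a, b in zip(matched, matched[1:]):
        if b == a + 1:
            dh, ds = NN[primer[a : a + 2]]
            total += dg37(dh, ds)
    for col in (matched[0], matched[-1]):
        dh, ds = INIT[primer[col]]
        total += dg37(dh, ds)
    if primer == rc(region):
        total += dg37(*SYM)
    return total


def find_sites(primer: str, records: dict, k: int, min_dg: float):
    """Naive full scan: (db_id, strand, three_prime, five_prime, dg)."""
    seed = primer[-k:]
    L = len(primer)
    out = []
    for rid, seq in records.items():
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] == seed:
                t = i + k - 1
                if t - L + 1 >= 0:
                    dg = site_dg(primer, seq[t - L + 1 : t + 1])
                    if dg <= min_dg:
                        out.append((rid, "+", t, t - L + 1, dg))
            if seq[i : i + k] == rc(seed):
                u = i
                if u + L <= len(seq):
                    dg = site_dg(rc(primer), seq[u : u + L])
                    if dg <= min_dg:
                        out.append((rid, "-", u, u + L - 1, dg))
    out.sort()
    return out


def amplicons(sites_f, sites_r, max_size):
    """(db_id, f_five, r_five, size) for plus sites upstream of minus sites."""
    out = []
    for rid_f, strand_f, t3f, t5f, _ in sites_f:
        if strand_f != "+":
            continue
        for rid_r, strand_r, t3r, t5r, _ in sites_r:
            if strand_r != "-" or rid_r != rid_f:
                continue
            if t3f >= t3r:
                continue
            size = t5r - t5f + 1
            if 1 <= size <= max_size:
                out.append((rid_f, t5f, t5r, size))
    out.sort()
    return out


def pair_amplicons(sites_a, sites_b, max_size):
    out = amplicons(sites_a, sites_b, max_size)
    if sites_a is not sites_b:
        out = sorted(out + amplicons(sites_b, sites_a, max_size))
    return out


def cross_ok(ps_i, ps_j, records: dict, k: int, min_dg: float,
             max_size: int, dimer_cutoff: float) -> bool:
    """Composite referee for two primer sets (package PrimerSet objects used
    only as coordinate/sequence containers; every decision recomputed here)."""
    prim = {
        "fi": ps_i.forward.sequence, "ri": ps_i.reverse.sequence,
        "fj": ps_j.forward.sequence, "rj": ps_j.reverse.sequence,
    }
    sites = {name: find_sites(seq, records, k, min_dg) for name, seq in prim.items()}

    def own_ok(ps, f, r):
        amps = pair_amplicons(sites[f], sites[r], max_size)
        intended = [a for a in amps if a[0] == ps.template_id
                    and a[1] == ps.forward.start and a[2] == ps.reverse.start
                    and a[3] == ps.amplicon_size]
        return len(intended) == 1 and len(amps) == 1

    if not own_ok(ps_i, "fi", "ri") or not own_ok(ps_j, "fj", "rj"):
        return False
    seqs = list(prim.values())
    for a, b in itertools.combinations_with_replacement(seqs, 2):
        if dimer_dg(a, b) <= dimer_cutoff:
            return False
    for a, b in (("fi", "fj"), ("ri", "rj"), ("fi", "rj"), ("ri", "fj")):
        if pair_amplicons(sites[a], sites[b], max_size):
            return False
    return True


# --- search --------------------------------------------------------------------

def brute_force_pscs(candidate_sets, compatible, minbs, positions):
    """All valid combinations (one PS per template), sorted by total penalty.

    ``compatible(a, b)`` is the edge predicate; ``positions(size)`` the gel
    mapping.  Returns a list of (total_penalty, combo tuple).
    """
    out = []
    for combo in itertools.product(*candidate_sets):
        ok = True
        for a, b in itertools.combinations(combo, 2):
            if not compatible(a, b):
                ok = False
                break
        if ok and len(combo) > 1:
            pos = [positions(ps.amplicon_size) for ps in combo]
            spacing = min(abs(pos[i] - pos[j])
                          for i in range(len(pos)) for j in range(i + 1, len(pos)))
            if spacing < minbs:
                ok = False
        if ok:
            out.append((sum(ps.penalty for ps in combo), combo))
    out.sort(key=lambda t: t[0])
    return out
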