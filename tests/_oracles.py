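"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: seed sites are found by
exhaustive per-offset base-pairing checks, TMM is a separate literal
transcription of the published formula, BH follows the sort-based
definition, and the Poisson exact test enumerates the binomial conditional
distribution with scipy's binom pmf.
"""

import numpy as np
import scipy.stats as ss

#: Watson-Crick pairing of a miRNA base (RNA) against a target base (DNA)
PAIR = {"A": "T", "C": "G", "G": "C", "U": "A"}


def oracle_sites(utr: str, mirna_seq: str) -> list[tuple[int, int, str]]:
    """All strong seed sites by exhaustive antiparallel complementarity.

    Returns (start, end, type) tuples; one call per offset with the
    strongest type, and a 7mer-A1 that is the tail of an 8mer is subsumed.
    """
    u = utr.strip().upper().replace("U", "T")
    mir = mirna_seq.strip().upper().replace("T", "U")
    L = len(u)

    def pairs(mirna_pos_1based: int, target_char: str) -> bool:
        return PAIR.get(mir[mirna_pos_1based - 1], "?") == target_char

    found: dict[int, tuple[str, int]] = {}
    for i in range(L):
        # 8mer: target[k] pairs miRNA nt (8-k) for k=0..6, then a literal A
        if i + 8 <= L and u[i + 7] == "A" and all(pairs(8 - k, u[i + k]) for k in range(7)):
            found[i] = ("8mer", 8)
        elif i + 7 <= L and all(pairs(8 - k, u[i + k]) for k in range(7)):
            found[i] = ("7mer-m8", 7)
        elif i + 7 <= L and u[i + 6] == "A" and all(pairs(7 - k, u[i + k]) for k in range(6)):
            if not (i >= 1 and found.get(i - 1, ("", 0))[0] == "8mer"):
                found[i] = ("7mer-A1", 7)
    return [(i, i + ln, t) for i, (t, ln) in sorted(found.items())]


def oracle_tmm(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Literal transcription of the TMM normalization formula."""
    lib = counts.sum(axis=0).astype(float)
    q75 = [np.percentile(counts[:, j] / lib[j], 75) for j in range(counts.shape[1])]
    ref = int(np.argmin([abs(q - np.mean(q75)) for q in q75]))
    fs = []
    for j in range(counts.shape[1]):
        o = counts[:, j].astype(float)
        r = counts[:, ref].astype(float)
        mask = (o > 0) & (r > 0)
        o, r = o[mask], r[mask]
        log_r = np.log2((o / lib[j]) / (r / lib[ref]))
        abs_e = 0.5 * np.log2((o / lib[j]) * (r / lib[ref]))
        v = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        if len(log_r) < 2 or np.max(np.abs(log_r)) < 1e-6:
            fs.append(1.0)
            continue
        n = len(log_r)
        rank_l, rank_a = ss.rankdata(log_r), ss.rankdata(abs_e)
        lo_l = np.floor(n * trim_m) + 1
        lo_s = np.floor(n * trim_a) + 1
        keep = (
            (rank_l >= lo_l) & (rank_l <= n + 1 - lo_l)
            & (rank_a >= lo_s) & (rank_a <= n + 1 - lo_s)
        )
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
        fs.append(2.0 ** f)
    fs = np.asarray(fs)
    return fs / np.exp(np.mean(np.log(fs)))


def oracle_bh(pvalues) -> np.ndarray:
    """Direct sort-based Benjamini-Hochberg adjustment."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def oracle_binom_exact(a: int, b: int, n_a: int, n_b: int) -> float:
    """Exhaustive binomial conditional two-sided p (Poisson limit)."""
    s = a + b
    if s == 0:
        return 1.0
    pmf = ss.binom.pmf(np.arange(s + 1), s, n_a / (n_a + n_b))
    return float(min(1.0, 2.0 * min(pmf[: a + 1].sum(), pmf[a:].sum())))


def oracle_ddct(ct_rows, reference_genes):
    """Spreadsheet-style 2^-ddCt chain on a list of dict rows."""
    refs = {}
    for r in ct_rows:
        if r["gene"] in reference_genes:
            key = (r["fraction"], r["condition"], r["timepoint_h"], r["replicate"])
            refs.setdefault(key, []).append(r["ct"])
    dct = []
    for r in ct_rows:
        if r["gene"] in reference_genes:
            continue
        key = (r["fraction"], r["condition"], r["timepoint_h"], r["replicate"])
        dct.append({**r, "dct": r["ct"] - sum(refs[key]) / len(refs[key])})
    out = []
    for r in dct:
        base = [x["dct"] for x in dct
                if x["gene"] == r["gene"] and x["fraction"] == r["fraction"]
                and x["condition"] == r["condition"] and x["timepoint_h"] == 0]
        ddct = r["dct"] - sum(base) / len(base)
        out.append({**r, "abundance": 2.0 ** (-ddct)})
    return out
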