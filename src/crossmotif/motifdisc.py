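"""Expectation-maximization motif discovery (ZOOPS model).

The generative model: each sequence carries, with prior probability
``gamma``, exactly one occurrence of a width-W motif at a uniformly
chosen admissible start, emitted from a position probability matrix
(PPM); all remaining positions are emitted from a 0-order background.
With probability ``1 - gamma`` the whole sequence is background. EM
alternates a posterior over site locations (E-step) with re-estimation of
the PPM (with Dirichlet pseudocounts) and of gamma (M-step); the
penalized observed-data objective (log likelihood ratio plus the
pseudocount log-prior) is non-decreasing across iterations.

Repeated discovery masks the occurrences of each reported motif with a
neutral symbol that is excluded both from candidate site windows and from
background re-estimation, then searches again, so motifs are returned in
decreasing order of explanatory strength ("rank 1 = most probable").

Significance is an empirical permutation E-value: residues are shuffled
within each sequence, the same single-width EM search is re-run on each
shuffle, and the observed log-likelihood ratio is ranked among the null
ones. Multiple within-sequence copies of a motif (the model allows at
most one) are recovered by the separate scan step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import AMINO_ACIDS, MASK_CODE, N_AA, SequenceFamily, encode

NEG = -1.0e30
#: coarse width grid used by discover before local refinement
WIDTH_GRID = (6, 8, 11, 15, 21, 30)


@dataclass
class BackgroundModel:
    """0-order residue frequencies over the 20 canonical types."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.shape != (N_AA,) or abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 20 frequencies summing to 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(freqs=np.full(N_AA, 1.0 / N_AA))

    @classmethod
    def from_codes(cls, codes: list[np.ndarray], pseudocount: float = 1.0) -> "BackgroundModel":
        counts = np.full(N_AA, pseudocount)
        for c in codes:
            counts += np.bincount(c[c < N_AA], minlength=N_AA)[:N_AA]
        return cls(freqs=counts / counts.sum())


@dataclass
class MotifOccurrence:
    sequence_id: str
    family: str
    start: int  # 1-based
    probability: float = 1.0
    score: float | None = None


@dataclass
class Motif:
    ppm: np.ndarray  # (W, 20), rows sum to 1
    width: int
    consensus: str
    occurrences: list[MotifOccurrence]
    llr: float
    gamma: float
    e_value: float | None = None
    rank: int = 1
    trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=np.float64)
        if self.ppm.shape != (self.width, N_AA):
            raise ValueError("ppm shape does not match width")
        if not np.allclose(self.ppm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("ppm rows must sum to 1")


@dataclass
class _Dataset:
    """Concatenated encoded sequences with per-sequence window segments."""

    ids: list[str]
    families: list[str]
    codes: list[np.ndarray]

    def windows(self, W: int):
        keep = [i for i, c in enumerate(self.codes) if len(c) >= W]
        if len(keep) < len(self.codes):
            warnings.warn(
                f"{len(self.codes) - len(keep)} sequence(s) shorter than W={W} excluded"
            )
        if len(keep) < 2:
            raise ValueError(f"fewer than 2 sequences of length >= W={W}")
        cat = np.concatenate([self.codes[i] for i in keep])
        lengths = np.array([len(self.codes[i]) for i in keep])
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        m = lengths - W + 1
        win_pos = np.concatenate(
            [s + np.arange(mi) for s, mi in zip(starts, m)]
        )
        seg = np.concatenate([[0], np.cumsum(m)[:-1]])
        return keep, cat, win_pos, seg, m


def _as_dataset(seqs) -> _Dataset:
    if isinstance(seqs, _Dataset):
        return seqs
    if isinstance(seqs, SequenceFamily):
        return _Dataset(
            ids=list(seqs.ids),
            families=[r.family for r in seqs],
            codes=[encode(r.sequence) for r in seqs],
        )
    # plain list of strings
    return _Dataset(
        ids=[f"seq{i}" for i in range(len(seqs))],
        families=[""] * len(seqs),
        codes=[encode(s) for s in seqs],
    )


def _seed_candidates(ds: _Dataset, W: int, n_best: int) -> list[np.ndarray]:
    """Candidate seed words: substrings ranked by shared-3-mer abundance.

    A word whose 3-mers recur across many sequences is a cheap proxy for
    an enriched motif core; candidates are taken at stride W//2 so every
    planted instance overlaps some candidate by at least half its width.
    """
    for stride in (max(1, W // 2), 1):
        cands = _strided_candidates(ds, W, n_best, stride)
        if cands:
            return cands
    return []


def _strided_candidates(
    ds: _Dataset, W: int, n_best: int, stride: int
) -> list[np.ndarray]:
    tri_list = []
    for c in ds.codes:
        if len(c) < 3:
            tri_list.append(np.empty(0, dtype=np.int64))
            continue
        c64 = c.astype(np.int64)
        tri = c64[:-2] * 400 + c64[1:-1] * 20 + c64[2:]
        valid = (c64[:-2] < N_AA) & (c64[1:-1] < N_AA) & (c64[2:] < N_AA)
        tri[~valid] = -1
        tri_list.append(tri)
    allv = np.concatenate([t[t >= 0] for t in tri_list]) if tri_list else np.empty(0, int)
    counts = np.bincount(allv, minlength=8000) if len(allv) else np.zeros(8000, int)
    scored = []  # (negscore, seq idx, start)
    for si, (c, tri) in enumerate(zip(ds.codes, tri_list)):
        if len(c) < W:
            continue
        per_pos = np.where(tri >= 0, counts[np.maximum(tri, 0)], 0)
        csum = np.concatenate([[0], np.cumsum(per_pos)])
        win = csum[W - 2 :] - csum[: len(csum) - (W - 2)]  # sum over W-2 3-mers
        bad = np.concatenate([[0], np.cumsum(c >= N_AA)])
        word_valid = (bad[W:] - bad[: len(bad) - W]) == 0
        for j in range(0, len(c) - W + 1, stride):
            if word_valid[j]:
                scored.append((-int(win[j]), si, j))
    scored.sort()
    out, seen = [], set()
    for _, si, j in scored:
        word = ds.codes[si][j : j + W]
        key = word.tobytes()
        if key in seen:
            continue
        seen.add(key)
        out.append(word)
        if len(out) >= n_best:
            break
    return out


def _seed_ppm(word: np.ndarray, match: float = 0.6) -> np.ndarray:
    W = len(word)
    ppm = np.full((W, N_AA), (1.0 - match) / (N_AA - 1))
    ppm[np.arange(W), word] = match
    return ppm


def _em_core(
    cat, win_pos, seg, m, W, ppm, gamma, bg, pseudocount, max_iter, tol
):
    """Run EM from a given PPM; returns (ppm, gamma, per-window posterior,
    per-seq loglik-ratio, objective trace)."""
    n_seq = len(seg)
    logbg = np.log(bg.freqs)
    m_eff = None
    trace = []
    obj_prev = -np.inf
    gathered = [cat[win_pos + k] for k in range(W)]
    for _ in range(max_iter):
        # E-step: per-window log odds
        LO = np.full((W, 22), NEG)
        LO[:, :N_AA] = np.log(ppm) - logbg[None, :]
        G = np.zeros(len(win_pos))
        for k in range(W):
            G += LO[k][gathered[k]]
        if m_eff is None:
            valid = G > NEG / 2
            m_eff = np.add.reduceat(valid.astype(np.float64), seg)
        A = np.maximum.reduceat(G, seg)
        A_safe = np.where(A > NEG / 2, A, 0.0)
        A_rep = np.repeat(A_safe, m)
        S = np.add.reduceat(np.exp(np.maximum(G - A_rep, -745.0)), seg)
        has_win = m_eff > 0
        log_site = np.where(
            has_win, np.log(gamma) - np.log(np.maximum(m_eff, 1.0)), NEG
        )
        with np.errstate(divide="ignore"):
            ll = np.logaddexp(
                np.log1p(-gamma),
                np.where(has_win, log_site + A_safe + np.log(np.maximum(S, 1e-300)), NEG),
            )
        w = np.exp(G + np.repeat(log_site - ll, m))
        w[G < NEG / 2] = 0.0
        obj = float(ll.sum()) + pseudocount * float(np.log(ppm).sum())
        trace.append(obj)
        if abs(obj - obj_prev) < tol * (1.0 + abs(obj)):
            break
        obj_prev = obj
        # M-step
        counts = np.empty((W, N_AA))
        for k in range(W):
            counts[k] = np.bincount(gathered[k], weights=w, minlength=22)[:N_AA]
        ppm = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + N_AA * pseudocount
        )
        gamma = float(np.clip(np.add.reduceat(w, seg).mean(), 1e-6, 1.0 - 1e-6))
    return ppm, gamma, w, ll, trace


def em_motif(
    seqs,
    W: int,
    background: BackgroundModel | None = None,
    init: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-7,
    seed: int = 0,
    n_seeds: int = 20,
    pseudocount: float = 0.01,
    gamma0: float = 0.5,
    site_threshold: float = 0.5,
) -> Motif:
    """Fit a single fixed-width ZOOPS motif by expectation maximization.

    Initialisation seeds a PPM from each of the ``n_seeds`` top candidate
    substrings (shared-3-mer ranking), runs 5 EM iterations on each, and
    continues the best to convergence. Deterministic for a given input;
    ``seed`` is accepted for interface uniformity and reserved for
    stochastic initialisation variants.
    """
    ds = _as_dataset(seqs)
    keep, cat, win_pos, seg, m = ds.windows(W)
    bg = background or BackgroundModel.from_codes([ds.codes[i] for i in keep])
    if init is not None:
        starts_ppm = [np.asarray(init, dtype=np.float64)]
    else:
        cands = _seed_candidates(
            _Dataset(
                ids=[ds.ids[i] for i in keep],
                families=[ds.families[i] for i in keep],
                codes=[ds.codes[i] for i in keep],
            ),
            W,
            n_seeds,
        )
        if not cands:
            raise ValueError("no admissible seed substrings")
        starts_ppm = [_seed_ppm(c) for c in cands]
    best = None
    for p0 in starts_ppm:
        ppm, gamma, w, ll, trace = _em_core(
            cat, win_pos, seg, m, W, p0, gamma0, bg, pseudocount, 5, 0.0
        )
        score = trace[-1]
        if best is None or score > best[0]:
            best = (score, ppm, gamma)
    ppm, gamma, w, ll, trace = _em_core(
        cat, win_pos, seg, m, W, best[1], best[2], bg, pseudocount, max_iter, tol
    )
    # per-sequence best site
    occurrences = []
    for si in range(len(seg)):
        lo = seg[si]
        hi = seg[si] + m[si]
        if hi == lo:
            continue
        wseg = w[lo:hi]
        j = int(np.argmax(wseg))
        if wseg[j] >= site_threshold:
            occurrences.append(
                MotifOccurrence(
                    sequence_id=ds.ids[keep[si]],
                    family=ds.families[keep[si]],
                    start=j + 1,
                    probability=float(wseg[j]),
                )
            )
    consensus = "".join(AMINO_ACIDS[a] for a in ppm.argmax(axis=1))
    return Motif(
        ppm=ppm,
        width=W,
        consensus=consensus,
        occurrences=occurrences,
        llr=float(ll.sum()),
        gamma=gamma,
        trace=trace,
    )


def scan(motif: Motif, seqs, threshold: float = 0.0) -> list[MotifOccurrence]:
    """All sites with log-odds score (bits) >= threshold, any number per
    sequence; windows touching masked residues are skipped."""
    ds = _as_dataset(seqs)
    bg = BackgroundModel.from_codes(ds.codes)
    LO = np.full((motif.width, 22), NEG)
    LO[:, :N_AA] = np.log2(motif.ppm) - np.log2(bg.freqs)[None, :]
    out = []
    for sid, fam, c in zip(ds.ids, ds.families, ds.codes):
        if len(c) < motif.width:
            continue
        G = np.zeros(len(c) - motif.width + 1)
        for k in range(motif.width):
            G += LO[k][c[k : k + len(G)]]
        for j in np.nonzero(G >= threshold)[0]:
            out.append(
                MotifOccurrence(
                    sequence_id=sid,
                    family=fam,
                    start=int(j) + 1,
                    score=float(G[j]),
                )
            )
    return out


def permutation_evalue(
    motif: Motif,
    seqs,
    B: int = 99,
    seed: int = 0,
    n_tested: int = 1,
    **em_kwargs,
) -> float:
    """Empirical E-value by within-sequence residue shuffling.

    Residues (masked positions stay put) are shuffled within each
    sequence B times; the same single-width EM search is re-run on each
    shuffle and E = n_tested * (1 + #{null llr >= observed llr}) / (B+1).
    Use the same EM keyword settings as the observed fit so the null
    search has the same power.
    """
    if B < 19:
        raise ValueError("B must be >= 19")
    ds = _as_dataset(seqs)
    rng = np.random.default_rng(seed)
    exceed = 0
    em_kwargs.setdefault("n_seeds", 5)
    em_kwargs.setdefault("max_iter", 30)
    for b in range(B):
        shuffled = []
        for c in ds.codes:
            c2 = c.copy()
            idx = np.nonzero(c2 < N_AA)[0]
            c2[idx] = c2[idx[rng.permutation(len(idx))]]
            shuffled.append(c2)
        null_ds = _Dataset(ids=ds.ids, families=ds.families, codes=shuffled)
        null = em_motif(null_ds, motif.width, **em_kwargs)
        if null.llr >= motif.llr:
            exceed += 1
    return n_tested * (1 + exceed) / (B + 1)


def _mask(ds: _Dataset, motif: Motif) -> None:
    by_id = {sid: i for i, sid in enumerate(ds.ids)}
    targets = motif.occurrences
    if not targets and motif.occurrences is not None:
        return
    for occ in targets:
        c = ds.codes[by_id[occ.sequence_id]]
        c[occ.start - 1 : occ.start - 1 + motif.width] = MASK_CODE


def discover(
    seqs,
    w_min: int = 6,
    w_max: int = 30,
    n_motifs: int = 1,
    seed: int = 0,
    n_perms: int = 0,
    refine: bool = True,
    adjust_by_permutation: bool = False,
    **em_kwargs,
) -> list[Motif]:
    """Repeated motif discovery with masking.

    For each rank, the best single-width motif over a coarse width grid
    (optionally refined by +/-2 around the grid optimum) is selected by
    log-likelihood ratio per column; with ``adjust_by_permutation`` the
    grid selection instead minimises the permutation E-value (costly).
    The chosen motif's occurrences are masked before the next rank. With
    ``n_perms`` >= 19 each reported motif carries a permutation E-value.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    if not 6 <= w_min <= w_max <= 30:
        raise ValueError("widths must satisfy 6 <= w_min <= w_max <= 30")
    ds = _as_dataset(seqs)
    work = _Dataset(ids=ds.ids, families=ds.families, codes=[c.copy() for c in ds.codes])
    grid = [w for w in WIDTH_GRID if w_min <= w <= w_max]
    if w_min not in grid:
        grid.insert(0, w_min)
    if w_max not in grid:
        grid.append(w_max)
    motifs: list[Motif] = []
    for rank in range(1, n_motifs + 1):
        admissible = [w for w in grid if any(len(c) >= w for c in work.codes)]
        if not admissible:
            raise ValueError("no admissible motif width for these sequences")
        fits = {}
        for w in admissible:
            try:
                fits[w] = em_motif(work, w, seed=seed, **em_kwargs)
            except ValueError:
                continue  # width not fittable on the masked residue budget
        admissible = [w for w in admissible if w in fits]
        if not admissible:
            raise ValueError("no admissible motif width for these sequences")
        if adjust_by_permutation and n_perms >= 19:
            evals = {
                w: permutation_evalue(fits[w], work, B=n_perms, seed=seed + 7 * w)
                for w in admissible
            }
            w_best = min(admissible, key=lambda w: (evals[w], -fits[w].llr / w))
        else:
            w_best = max(admissible, key=lambda w: fits[w].llr / w)
        best = fits[w_best]
        if refine:
            for w in range(max(w_min, w_best - 2), min(w_max, w_best + 2) + 1):
                if w in fits or not any(len(c) >= w for c in work.codes):
                    continue
                try:
                    cand = em_motif(work, w, seed=seed, **em_kwargs)
                except ValueError:
                    continue
                if cand.llr / w > best.llr / best.width:
                    best = cand
        if n_perms >= 19 and best.e_value is None:
            best.e_value = permutation_evalue(
                best, work, B=n_perms, seed=seed + 13 * rank
            )
        best.rank = rank
        motifs.append(best)
        if rank < n_motifs:
            if best.occurrences:
                _mask(work, best)
            else:
                # nothing confidently placed: mask the single best-scoring
                # site so the search cannot stall on the same solution
                hits = scan(best, work, threshold=-1e9)
                if hits:
                    top = max(hits, key=lambda o: o.score)
                    _mask(work, Motif(
                        ppm=best.ppm, width=best.width, consensus=best.consensus,
                        occurrences=[top], llr=best.llr, gamma=best.gamma,
                    ))
    return motifs


# ---------------------------------------------------------------------------
# MEME minimal format


def write_meme(motifs: list[Motif], background: BackgroundModel, path: str | Path) -> None:
    """Write motifs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {AMINO_ACIDS}\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{a} {f:.5f}" for a, f in zip(AMINO_ACIDS, background.freqs))
            + "\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF motif_{m.rank} {m.consensus}\n")
            ev = f"{m.e_value:.4g}" if m.e_value is not None else "0"
            fh.write(
                f"letter-probability matrix: alength= {N_AA} w= {m.width} "
                f"nsites= {len(m.occurrences)} E= {ev}\n"
            )
            for row in m.ppm:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> tuple[list[Motif], BackgroundModel]:
    """Parse a MEME minimal motif file written by :func:`write_meme`."""
    lines = Path(path).read_text().splitlines()
    bg = BackgroundModel.uniform()
    motifs: list[Motif] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            freqs = np.zeros(N_AA)
            for a, f in zip(parts[0::2], parts[1::2]):
                freqs[AMINO_ACIDS.index(a)] = float(f)
            bg = BackgroundModel(freqs=freqs / freqs.sum())
            i += 2
        elif line.startswith("MOTIF"):
            header = lines[i + 1].split()
            w = int(header[header.index("w=") + 1])
            ev = float(header[header.index("E=") + 1]) if "E=" in header else None
            rows = [
                [float(x) for x in lines[i + 2 + k].split()] for k in range(w)
            ]
            ppm = np.array(rows)
            ppm = ppm / ppm.sum(axis=1, keepdims=True)
            consensus = "".join(AMINO_ACIDS[a] for a in ppm.argmax(axis=1))
            motifs.append(
                Motif(
                    ppm=ppm,
                    width=w,
                    consensus=consensus,
                    occurrences=[],
                    llr=0.0,
                    gamma=0.0,
                    e_value=ev,
                    rank=len(motifs) + 1,
                )
            )
            i += 2 + w
        else:
            i += 1
    return motifs, bg


def write_occurrences(motifs: list[Motif], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_rank\tsequence_id\tfamily\tstart\tend\tprobability\n")
        for m in motifs:
            for occ in m.occurrences:
                fh.write(
                    f"{m.rank}\t{occ.sequence_id}\t{occ.family}\t{occ.start}\t"
                    f"{occ.start + m.width - 1}\t{occ.probability:.4f}\n"
                )
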