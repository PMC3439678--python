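"""Cluster profile HMMs anchored on structural templates.

Each annotating cluster is summarised by a profile hidden Markov model
whose match states are the residues of the cluster's anchor template, so
that every structurally observed position owns a match state and can carry
its metal-coordination annotation into any member sequence.  The cluster
multiple alignment is a star alignment around the anchor; emissions are
smoothed with background-weighted pseudocounts, transitions with add-one
counts, and members are threaded through the model with a global Viterbi
alignment scored in bits against a uniform background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import align
from .blosum import AMINO_ACIDS

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
NEG_INF = -1e30

# state codes
M_STATE, I_STATE, D_STATE = 0, 1, 2
_STATE_NAME = {M_STATE: "M", I_STATE: "I", D_STATE: "D"}


@dataclass
class StarMsa:
    """A star multiple alignment around an anchor row.

    Rows are (accession, aligned string) with equal lengths; the anchor row
    is never gapped in its own match columns (columns where it carries a
    residue), and member insertions relative to the anchor live in insert
    columns where the anchor is gapped.
    """

    rows: list
    anchor_index: int = 0

    def __post_init__(self):
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("MSA rows have unequal lengths")

    @property
    def anchor_row(self) -> str:
        return self.rows[self.anchor_index][1]

    @property
    def match_columns(self) -> list[int]:
        return [c for c, ch in enumerate(self.anchor_row) if ch != "-"]

    def position_to_column(self, row_index: int) -> dict[int, int]:
        """1-based sequence position -> column, for one row."""
        out, pos = {}, 0
        for col, ch in enumerate(self.rows[row_index][1]):
            if ch != "-":
                pos += 1
                out[pos] = col
        return out

    def accession_row(self, accession: str) -> int:
        for i, (acc, _) in enumerate(self.rows):
            if acc == accession:
                return i
        raise KeyError(accession)


def build_cluster_msa(members, anchor) -> StarMsa:
    """Star alignment of cluster members around the anchor template.

    Every member is globally aligned to the anchor (BLOSUM62, gap open 11 /
    extend 1); member-member columns are induced through the anchor.  The
    anchor is row 0.  Members sharing the anchor's accession are skipped.
    """
    if anchor is None:
        raise ValueError("cluster has no anchor template")
    n = len(anchor.sequence)
    others = [m for m in members if m.accession != anchor.accession]
    # per member: residue aligned to each anchor position, and insertions
    # before each anchor position (index 0..n, n meaning C-terminal)
    aligned_rows, inserts = [], [[""] * (n + 1) for _ in others]
    for idx, member in enumerate(others):
        aln = align.global_align(anchor.sequence, member.sequence)
        row = ["-"] * n
        for i, j in aln.pairs:
            if i is not None and j is not None:
                row[i] = member.sequence[j]
            elif i is None:
                # insertion: attach before the next anchor position
                nxt = next((a for a, b in aln.pairs if a is not None and b is not None
                            and b > j), None)
                k = nxt if nxt is not None else n
                inserts[idx][k] += member.sequence[j]
        aligned_rows.append(row)

    ins_len = [max((len(inserts[r][k]) for r in range(len(others))), default=0)
               for k in range(n + 1)]
    rows = []
    anchor_cols = []
    for k in range(n):
        anchor_cols.append("-" * ins_len[k] + anchor.sequence[k])
    anchor_str = "".join(anchor_cols) + "-" * ins_len[n]
    rows.append((anchor.accession, anchor_str))
    for r, member in enumerate(others):
        parts = []
        for k in range(n):
            parts.append(inserts[r][k].ljust(ins_len[k], "-") + aligned_rows[r][k])
        parts.append(inserts[r][n].ljust(ins_len[n], "-"))
        rows.append((member.accession, "".join(parts)))
    return StarMsa(rows=rows, anchor_index=0)


@dataclass
class ProfileHMM:
    """Match/insert/delete profile HMM with a match-to-template map.

    ``match_emissions[k]`` (k = 1..M) and ``insert_emissions[k]``
    (k = 0..M) are distributions over the 20 amino acids;
    ``transitions[k, s, t]`` is P(move t | state s at column k) with
    s, t in {M, I, D} and "move to D" impossible at k = M.
    ``match_to_ref`` maps match index k to the anchor template's 1-based
    reference position.
    """

    M: int
    match_emissions: np.ndarray  # (M+1, 20); row 0 unused
    insert_emissions: np.ndarray  # (M+1, 20)
    transitions: np.ndarray  # (M+1, 3, 3)
    match_to_ref: dict
    anchor_accession: str = ""

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("profile HMM needs at least one match state")
        self.validate()

    def validate(self, tol: float = 1e-9) -> None:
        for k in range(1, self.M + 1):
            if abs(self.match_emissions[k].sum() - 1.0) > tol:
                raise ValueError(f"match emissions at {k} do not normalise")
        for k in range(self.M + 1):
            if abs(self.insert_emissions[k].sum() - 1.0) > tol:
                raise ValueError(f"insert emissions at {k} do not normalise")
            for s in range(3):
                if k == 0 and s == D_STATE:
                    continue  # D0 does not exist
                if abs(self.transitions[k, s].sum() - 1.0) > tol:
                    raise ValueError(f"transitions from ({k},{s}) do not normalise")
        refs = [self.match_to_ref[k] for k in sorted(self.match_to_ref)]
        if any(b <= a for a, b in zip(refs, refs[1:])):
            raise ValueError("match-to-template map must be strictly increasing")


@dataclass(frozen=True)
class AlignmentPath:
    """A Viterbi state path: (state kind, column k, 1-based target position)."""

    accession: str
    states: tuple  # ("M"|"I"|"D", k, pos or None)
    score: float  # bits

    def target_position_of_match(self, k: int):
        for kind, col, pos in self.states:
            if col == k and kind == "M":
                return pos
            if col == k and kind == "D":
                return None
        return None


def _row_state_path(row: str, is_match_col) -> list:
    """State sequence (code, k) of one MSA row under the anchor columns."""
    path, k = [], 0
    for col, ch in enumerate(row):
        if is_match_col[col]:
            k += 1
            path.append((M_STATE, k) if ch != "-" else (D_STATE, k))
        elif ch != "-":
            path.append((I_STATE, k))
    return path


def build_profile_hmm(msa: StarMsa, anchor_row: int | None = None,
                      pseudocount: float = 1.0,
                      background: np.ndarray | None = None) -> ProfileHMM:
    """Estimate a profile HMM from a star MSA.

    Match states are the columns where the anchor row carries a residue
    (structure-anchored match assignment).  Emissions are estimated as
    (counts + pseudocount x background) / (total + pseudocount); transitions
    with Laplace add-one over the allowed successors.
    """
    if anchor_row is None:
        anchor_row = msa.anchor_index
    if not msa.rows:
        raise ValueError("empty MSA")
    ncol = len(msa.rows[0][1])
    anchor = msa.rows[anchor_row][1]
    is_match_col = [anchor[c] != "-" for c in range(ncol)]
    match_cols = [c for c in range(ncol) if is_match_col[c]]
    M = len(match_cols)
    if M == 0:
        raise ValueError("anchor row is all gaps")
    bg = np.full(20, 1 / 20) if background is None else np.asarray(background, float)

    m_counts = np.zeros((M + 1, 20))
    i_counts = np.zeros((M + 1, 20))
    t_counts = np.zeros((M + 1, 3, 3))
    for _, row in msa.rows:
        path = _row_state_path(row, is_match_col)
        residues = [ch for ch in row if ch != "-"]
        ri = 0
        prev = (M_STATE, 0)  # begin
        for state, k in path:
            if state in (M_STATE, I_STATE):
                ch = residues[ri]
                ri += 1
                idx = _AA_INDEX.get(ch)
                if idx is not None:
                    (m_counts if state == M_STATE else i_counts)[k, idx] += 1
            t_counts[prev[1], prev[0], _move_code(prev, (state, k))] += 1
            prev = (state, k)
        t_counts[prev[1], prev[0], M_STATE] += 1  # to end

    denom_m = m_counts.sum(axis=1, keepdims=True) + pseudocount
    denom_i = i_counts.sum(axis=1, keepdims=True) + pseudocount
    with np.errstate(invalid="ignore", divide="ignore"):
        match_em = np.where(denom_m > 0, (m_counts + pseudocount * bg) / denom_m, bg)
        insert_em = np.where(denom_i > 0, (i_counts + pseudocount * bg) / denom_i, bg)
    match_em[0] = bg  # row 0 unused but kept normalised

    trans = np.zeros((M + 1, 3, 3))
    for k in range(M + 1):
        for s in range(3):
            allowed = [M_STATE, I_STATE] + ([D_STATE] if k < M else [])
            row_counts = t_counts[k, s, allowed] + 1.0  # Laplace add-one
            trans[k, s, allowed] = row_counts / row_counts.sum()

    # the k-th match state is the k-th anchor residue, i.e. anchor position k
    match_to_ref = {k: k for k in range(1, M + 1)}

    hmm = ProfileHMM(
        M=M, match_emissions=match_em, insert_emissions=insert_em,
        transitions=trans, match_to_ref=match_to_ref,
        anchor_accession=msa.rows[anchor_row][0],
    )
    return hmm


def _move_code(prev, nxt) -> int:
    """Transition 'move' index: to next match, stay-insert, or next delete."""
    state, k = nxt
    if state == M_STATE:
        return M_STATE
    if state == I_STATE:
        return I_STATE
    return D_STATE


def viterbi_align(hmm: ProfileHMM, target: str,
                  accession: str = "") -> AlignmentPath:
    """Best global state path of ``target`` through the profile, in bits.

    Log-odds scoring against a uniform background; residues outside the
    20-letter alphabet emit at background (score contribution zero).
    Ties prefer match over delete over insert.
    """
    if not target:
        raise ValueError("empty target sequence")
    L, M = len(target), hmm.M
    bg = 1 / 20
    x = np.array([_AA_INDEX.get(ch, -1) for ch in target])

    def log2(a):
        with np.errstate(divide="ignore"):
            out = np.log2(a, where=a > 0, out=np.full_like(a, NEG_INF, dtype=float))
        out[a <= 0] = NEG_INF
        return out

    lt = log2(hmm.transitions)
    lm = log2(hmm.match_emissions / bg)
    li = log2(hmm.insert_emissions / bg)
    # emission score per (k, i): 0 for unknown residues
    m_emit = np.zeros((M + 1, L))
    i_emit = np.zeros((M + 1, L))
    known = x >= 0
    m_emit[:, known] = lm[:, x[known]]
    i_emit[:, known] = li[:, x[known]]

    VM = np.full((M + 1, L + 1), NEG_INF)
    VI = np.full((M + 1, L + 1), NEG_INF)
    VD = np.full((M + 1, L + 1), NEG_INF)
    PM = np.zeros((M + 1, L + 1), dtype=np.int8)
    PI = np.zeros((M + 1, L + 1), dtype=np.int8)
    PD = np.zeros((M + 1, L + 1), dtype=np.int8)
    VM[0, 0] = 0.0

    def best3(vm, vi, vd):
        # preference on ties: M > D > I
        best, ptr = vm, np.zeros_like(vm, dtype=np.int8)
        take = vd > best
        best = np.where(take, vd, best)
        ptr = np.where(take, np.int8(D_STATE), ptr)
        take = vi > best
        best = np.where(take, vi, best)
        ptr = np.where(take, np.int8(I_STATE), ptr)
        return best, ptr

    for k in range(0, M + 1):
        if k >= 1:
            # match: from (k-1, i-1)
            src, ptr = best3(VM[k - 1, :-1] + lt[k - 1, M_STATE, M_STATE],
                             VI[k - 1, :-1] + lt[k - 1, I_STATE, M_STATE],
                             VD[k - 1, :-1] + lt[k - 1, D_STATE, M_STATE])
            VM[k, 1:] = src + m_emit[k, :]
            PM[k, 1:] = ptr
            # delete: from (k-1, i)
            src, ptr = best3(VM[k - 1, :] + lt[k - 1, M_STATE, D_STATE],
                             VI[k - 1, :] + lt[k - 1, I_STATE, D_STATE],
                             VD[k - 1, :] + lt[k - 1, D_STATE, D_STATE])
            VD[k, :] = src
            PD[k, :] = ptr
        # insert: from (k, i-1) — sequential in i
        ltMI, ltII, ltDI = lt[k, M_STATE, I_STATE], lt[k, I_STATE, I_STATE], lt[k, D_STATE, I_STATE]
        for i in range(1, L + 1):
            vm = VM[k, i - 1] + ltMI
            vd = VD[k, i - 1] + ltDI
            vi = VI[k, i - 1] + ltII
            best, ptr = vm, M_STATE
            if vd > best:
                best, ptr = vd, D_STATE
            if vi > best:
                best, ptr = vi, I_STATE
            VI[k, i] = best + i_emit[k, i - 1]
            PI[k, i] = ptr

    finals = (VM[M, L] + lt[M, M_STATE, M_STATE],
              VI[M, L] + lt[M, I_STATE, M_STATE],
              VD[M, L] + lt[M, D_STATE, M_STATE])
    # tie preference M > D > I
    state, score = M_STATE, finals[0]
    if finals[2] > score:
        state, score = D_STATE, finals[2]
    if finals[1] > score:
        state, score = I_STATE, finals[1]

    # traceback
    states = []
    k, i = M, L
    while not (k == 0 and i == 0 and state == M_STATE):
        if state == M_STATE:
            states.append(("M", k, i))
            ptr = PM[k, i]
            k, i = k - 1, i - 1
        elif state == I_STATE:
            states.append(("I", k, i))
            ptr = PI[k, i]
            i -= 1
        else:
            states.append(("D", k, None))
            ptr = PD[k, i]
            k -= 1
        state = int(ptr)
        if k < 0 or i < 0:
            raise RuntimeError("Viterbi traceback escaped the DP table")
    return AlignmentPath(accession=accession, states=tuple(reversed(states)),
                         score=float(score))


def template_position_to_target(hmm: ProfileHMM, path: AlignmentPath,
                                template_position: int):
    """Target position aligned to a template (anchor) position, or "deleted".

    Raises :class:`NotTransferableError` when the template position owns no
    match state (residue unresolved in the structure).
    """
    from .errors import NotTransferableError

    inverse = {ref: k for k, ref in hmm.match_to_ref.items()}
    k = inverse.get(template_position)
    if k is None:
        raise NotTransferableError(
            f"template position {template_position} has no match state")
    for kind, col, pos in path.states:
        if col == k and kind == "M":
            return pos
        if col == k and kind == "D":
            return "deleted"
    raise RuntimeError(f"path does not visit column {k}")


def save_hmm(hmm: ProfileHMM, path) -> None:
    """Serialise to a plain-text per-cluster model file."""
    with open(path, "w") as fh:
        fh.write(f"# mgsite profile HMM\nM\t{hmm.M}\nALPHABET\t{AMINO_ACIDS}\n")
        fh.write(f"ANCHOR\t{hmm.anchor_accession}\n")
        fh.write("MATCH_TO_REF\t" + ",".join(
            f"{k}:{v}" for k, v in sorted(hmm.match_to_ref.items())) + "\n")
        for k in range(1, hmm.M + 1):
            fh.write("ME\t%d\t%s\n" % (k, "\t".join(
                f"{p:.17e}" for p in hmm.match_emissions[k])))
        for k in range(hmm.M + 1):
            fh.write("IE\t%d\t%s\n" % (k, "\t".join(
                f"{p:.17e}" for p in hmm.insert_emissions[k])))
        for k in range(hmm.M + 1):
            for s in range(3):
                fh.write("TR\t%d\t%s\t%s\n" % (k, _STATE_NAME[s], "\t".join(
                    f"{p:.17e}" for p in hmm.transitions[k, s])))


def load_hmm(path) -> ProfileHMM:
    M = None
    match_to_ref = {}
    anchor = ""
    me, ie, tr = {}, {}, {}
    code = {"M": M_STATE, "I": I_STATE, "D": D_STATE}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "M":
                M = int(parts[1])
            elif parts[0] == "ANCHOR":
                anchor = parts[1] if len(parts) > 1 else ""
            elif parts[0] == "MATCH_TO_REF":
                for pair in parts[1].split(","):
                    k, v = pair.split(":")
                    match_to_ref[int(k)] = int(v)
            elif parts[0] == "ME":
                me[int(parts[1])] = [float(p) for p in parts[2:]]
            elif parts[0] == "IE":
                ie[int(parts[1])] = [float(p) for p in parts[2:]]
            elif parts[0] == "TR":
                tr[(int(parts[1]), code[parts[2]])] = [float(p) for p in parts[3:]]
    match_em = np.full((M + 1, 20), 1 / 20)
    insert_em = np.full((M + 1, 20), 1 / 20)
    trans = np.zeros((M + 1, 3, 3))
    for k, row in me.items():
        match_em[k] = row
    for k, row in ie.items():
        insert_em[k] = row
    for (k, s), row in tr.items():
        trans[k, s] = row
    trans[0, D_STATE] = trans[0, M_STATE]  # placeholder row; D0 absent
    return ProfileHMM(M=M, match_emissions=match_em, insert_emissions=insert_em,
                      transitions=trans, match_to_ref=match_to_ref,
                      anchor_accession=anchor)
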