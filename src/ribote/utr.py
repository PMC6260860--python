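"""5'UTR extraction, minimum-free-energy folding, and TE-class comparison.

The folder is a self-contained Zuker-style dynamic program over a
simplified nearest-neighbor energy model: stacking energies for the six
canonical pair types (AU, UA, GC, CG, GU, UG) from a shipped parameter
table, linear hairpin/interior-loop penalties, a linear multiloop model,
a minimum hairpin loop of 3 nt and no pseudoknots.  Absolute free energies
are therefore not comparable to full Turner-model folders; relative
comparisons between sequence classes are the intended use, and the energy
table is pluggable so a different parameterization can be substituted.

Tie-breaking in the traceback is deterministic: candidate decompositions
are scanned in a fixed order (hairpin, then inner pairs by ascending
(i, j), then multiloop), and at the exterior level a pair is introduced
only when it strictly lowers the energy, so delta_g == 0 exactly when the
structure has no pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .io_formats import GeneModel, ValidationError

_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")
_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}
INF = float("inf")


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor stack energies plus linear loop penalties (kcal/mol)."""

    stack: dict          # (outer pair, inner pair) -> stacking energy
    hairpin_base: float
    hairpin_per_nt: float        # per unpaired nt beyond the 3-nt minimum
    interior_base: float
    interior_per_nt: float
    multi_base: float
    multi_branch: float
    multi_unpaired: float
    max_interior: int
    min_hairpin: int

    def hairpin(self, n_unpaired: int) -> float:
        return self.hairpin_base + self.hairpin_per_nt * (n_unpaired
                                                          - self.min_hairpin)

    def interior(self, n_unpaired: int) -> float:
        return self.interior_base + self.interior_per_nt * n_unpaired


def load_energy_model() -> EnergyModel:
    """Load the packaged nearest-neighbor table."""
    data = resources.files("ribote") / "data"
    stack: dict[tuple[str, str], float] = {}
    lines = (data / "stack_energies.tsv").read_text().strip().splitlines()
    header = lines[0].split("\t")[1:]
    for line in lines[1:]:
        fields = line.split("\t")
        outer = fields[0]
        for inner, val in zip(header, fields[1:]):
            stack[(outer, inner)] = float(val)
    params: dict[str, float] = {}
    for line in (data / "loop_params.tsv").read_text().strip().splitlines()[1:]:
        k, v = line.split("\t")
        params[k] = float(v)
    return EnergyModel(stack=stack,
                       hairpin_base=params["hairpin_base"],
                       hairpin_per_nt=params["hairpin_per_nt"],
                       interior_base=params["interior_base"],
                       interior_per_nt=params["interior_per_nt"],
                       multi_base=params["multi_base"],
                       multi_branch=params["multi_branch"],
                       multi_unpaired=params["multi_unpaired"],
                       max_interior=int(params["max_interior"]),
                       min_hairpin=int(params["min_hairpin"]))


_DEFAULT_MODEL: EnergyModel | None = None


def default_energy_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_energy_model()
    return _DEFAULT_MODEL


@dataclass
class UTRFold:
    gene_id: str | None
    sequence: str
    structure: str
    delta_g: float
    flagged_short: bool = False

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _pair_name(a: str, b: str) -> str | None:
    p = a + b
    return p if p in _PAIRS else None


def extract_utr5(annotation: list[GeneModel],
                 genome: dict[str, str]) -> dict[str, str]:
    """Strand-aware 5'UTR sequences in the RNA alphabet.

    Minus-strand intervals are reverse-complemented so the result always
    reads 5'->3'; DNA T is transcribed to U.  Genes without a known TSS or
    with an empty 5'UTR are skipped.
    """
    out: dict[str, str] = {}
    for g in annotation:
        if not g.tss_known or g.utr5_length == 0:
            continue
        if g.contig not in genome:
            raise ValidationError(f"{g.gene_id}: contig {g.contig!r} not in genome")
        s, e = g.utr5_interval
        contig = genome[g.contig]
        if e > len(contig):
            raise ValidationError(f"{g.gene_id}: UTR interval beyond contig end")
        seq = contig[s:e].upper().replace("T", "U")
        if g.strand == "-":
            try:
                seq = "".join(_RC[c] for c in reversed(seq))
            except KeyError as exc:
                raise ValidationError(
                    f"{g.gene_id}: ambiguous base in UTR") from exc
        out[g.gene_id] = seq
    return out


def fold_mfe(sequence: str, model: EnergyModel | None = None,
             gene_id: str | None = None) -> UTRFold:
    """Minimum-free-energy fold of one RNA sequence.

    Returns the optimal structure in dot-bracket notation and its energy;
    an unstructured sequence gets all dots and delta_g = 0.  Sequences
    shorter than 8 nt are folded but flagged as trivially unstructured.
    """
    if model is None:
        model = default_energy_model()
    seq = sequence.upper()
    if len(seq) == 0:
        raise ValidationError("cannot fold an empty sequence")
    for i, c in enumerate(seq):
        if c not in "ACGU":
            raise ValidationError(f"invalid RNA character {c!r} at position {i}")
    n = len(seq)
    min_span = model.min_hairpin + 1          # j - i must be >= this to pair

    pairname = [[None] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + min_span, n):
            pairname[i][j] = _pair_name(seq[i], seq[j])

    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)

    for span in range(min_span, n):
        for i in range(0, n - span):
            j = i + span
            if pairname[i][j] is not None:
                best = model.hairpin(j - i - 1)
                # stacked pair / interior loop / bulge
                kmax = min(j - min_span - 1, i + 1 + model.max_interior)
                for k in range(i + 1, kmax + 1):
                    left = k - i - 1
                    if left > model.max_interior:
                        break
                    lmin = max(k + min_span, j - 1 - (model.max_interior - left))
                    for l in range(lmin, j):
                        if pairname[k][l] is None or V[k, l] == INF:
                            continue
                        unpaired = left + (j - l - 1)
                        if unpaired == 0:
                            e = model.stack[(pairname[i][j], pairname[k][l])] \
                                + V[k, l]
                        else:
                            e = model.interior(unpaired) + V[k, l]
                        if e < best:
                            best = e
                # multiloop: >= 2 branches inside (i, j)
                closing = model.multi_base + model.multi_branch
                for m in range(i + 2, j - 1):
                    if WM[i + 1, m] < INF and WM[m + 1, j - 1] < INF:
                        e = closing + WM[i + 1, m] + WM[m + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM: segment holding >= 1 multiloop branch
            cand = INF
            if WM[i + 1, j] < INF:
                cand = min(cand, WM[i + 1, j] + model.multi_unpaired)
            if WM[i, j - 1] < INF:
                cand = min(cand, WM[i, j - 1] + model.multi_unpaired)
            if V[i, j] < INF:
                cand = min(cand, V[i, j] + model.multi_branch)
            for m in range(i + 1, j):
                if WM[i, m] < INF and WM[m + 1, j] < INF:
                    cand = min(cand, WM[i, m] + WM[m + 1, j])
            WM[i, j] = cand

    # exterior loop: unpaired bases are free
    W = np.zeros(n + 1)            # W[t] = optimum for suffix seq[t:]
    for t in range(n - 1, -1, -1):
        best = W[t + 1]
        for l in range(t + min_span, n):
            if V[t, l] < INF:
                e = V[t, l] + W[l + 1]
                if e < best:
                    best = e
        W[t] = best

    structure = ["."] * n
    _trace_exterior(0, n, seq, model, V, WM, W, structure)
    delta_g = float(W[0])
    return UTRFold(gene_id=gene_id, sequence=seq,
                   structure="".join(structure), delta_g=round(delta_g, 10),
                   flagged_short=n < 8)


def _trace_exterior(t, n, seq, model, V, WM, W, structure):
    min_span = model.min_hairpin + 1
    while t < n:
        if W[t] == W[t + 1]:
            # a pair is introduced only when it strictly improves the energy
            t += 1
            continue
        placed = False
        for l in range(t + min_span, n):
            if V[t, l] < INF and V[t, l] + W[l + 1] == W[t]:
                _trace_pair(t, l, seq, model, V, WM, structure)
                t = l + 1
                placed = True
                break
        if not placed:       # numerical safety; cannot happen for exact sums
            t += 1


def _trace_pair(i, j, seq, model, V, WM, structure):
    structure[i], structure[j] = "(", ")"
    pairname_ij = _pair_name(seq[i], seq[j])
    min_span = model.min_hairpin + 1
    target = V[i, j]
    if target == model.hairpin(j - i - 1):
        return
    kmax = min(j - min_span - 1, i + 1 + model.max_interior)
    for k in range(i + 1, kmax + 1):
        left = k - i - 1
        if left > model.max_interior:
            break
        lmin = max(k + min_span, j - 1 - (model.max_interior - left))
        for l in range(lmin, j):
            pn = _pair_name(seq[k], seq[l])
            if pn is None or V[k, l] == INF:
                continue
            unpaired = left + (j - l - 1)
            if unpaired == 0:
                e = model.stack[(pairname_ij, pn)] + V[k, l]
            else:
                e = model.interior(unpaired) + V[k, l]
            if e == target:
                _trace_pair(k, l, seq, model, V, WM, structure)
                return
    closing = model.multi_base + model.multi_branch
    for m in range(i + 2, j - 1):
        if WM[i + 1, m] < INF and WM[m + 1, j - 1] < INF and \
                closing + WM[i + 1, m] + WM[m + 1, j - 1] == target:
            _trace_wm(i + 1, m, seq, model, V, WM, structure)
            _trace_wm(m + 1, j - 1, seq, model, V, WM, structure)
            return
    raise AssertionError("traceback failed to reproduce V(i,j)")


def _trace_wm(i, j, seq, model, V, WM, structure):
    target = WM[i, j]
    if i > j or target == INF:
        raise AssertionError("invalid WM traceback segment")
    if V[i, j] < INF and target == V[i, j] + model.multi_branch:
        _trace_pair(i, j, seq, model, V, WM, structure)
        return
    if i + 1 <= j and WM[i + 1, j] < INF and \
            target == WM[i + 1, j] + model.multi_unpaired:
        _trace_wm(i + 1, j, seq, model, V, WM, structure)
        return
    if i <= j - 1 and WM[i, j - 1] < INF and \
            target == WM[i, j - 1] + model.multi_unpaired:
        _trace_wm(i, j - 1, seq, model, V, WM, structure)
        return
    for m in range(i + 1, j):
        if WM[i, m] < INF and WM[m + 1, j] < INF and \
                target == WM[i, m] + WM[m + 1, j]:
            _trace_wm(i, m, seq, model, V, WM, structure)
            _trace_wm(m + 1, j, seq, model, V, WM, structure)
            return
    raise AssertionError("traceback failed to reproduce WM(i,j)")


@dataclass
class ClassComparison:
    """Free-energy comparison between two TE classes of 5'UTRs."""

    class_a: str
    class_b: str
    delta_g_a: np.ndarray
    delta_g_b: np.ndarray
    median_a: float
    median_b: float
    statistic: float
    p: float


def compare_classes(folds: dict[str, UTRFold], te_table,
                    classes: tuple[str, str] = ("up", "down")) -> ClassComparison:
    """Wilcoxon rank-sum comparison of fold ΔG between two TE classes.

    ``te_table`` is the classified TE table (``gene_id``, ``te_class``).
    """
    from .stats import wilcoxon_rank_sum

    cls_of = dict(zip(te_table["gene_id"], te_table["te_class"]))
    groups: dict[str, list[float]] = {c: [] for c in classes}
    for gid, fold in folds.items():
        c = cls_of.get(gid)
        if c in groups:
            groups[c].append(fold.delta_g)
    a, b = classes
    xa = np.asarray(groups[a], dtype=float)
    xb = np.asarray(groups[b], dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValidationError(
            f"both classes need >= 1 fold (got {xa.size} {a!r}, {xb.size} {b!r})")
    stat, p = wilcoxon_rank_sum(xa, xb)
    return ClassComparison(class_a=a, class_b=b, delta_g_a=xa, delta_g_b=xb,
                           median_a=float(np.median(xa)),
                           median_b=float(np.median(xb)),
                           statistic=stat, p=p)
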