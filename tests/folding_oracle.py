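"""Independent brute-force oracle for the MFE folder.

Enumerates every valid secondary structure (non-crossing canonical pairs,
hairpin loops >= 3 nt) of a short sequence and scores each by a direct
loop-decomposition evaluator, sharing only the parameter table with the
implementation under test — never its recursions.
"""

from ribote.utr import EnergyModel

CANONICAL = {"AU", "UA", "GC", "CG", "GU", "UG"}


def enumerate_structures(seq):
    """All sets of non-crossing canonical pairs with hairpin loops >= 3."""
    n = len(seq)

    def rec(i, j):
        if j - i < 0:
            return [[]]
        out = [s for s in rec(i + 1, j)]           # i unpaired
        for l in range(i + 4, j + 1):
            if seq[i] + seq[l] in CANONICAL:
                for inner in rec(i + 1, l - 1):
                    for rest in rec(l + 1, j):
                        out.append([(i, l)] + inner + rest)
        return out

    return rec(0, n - 1)


def structure_energy(seq, pairs, model: EnergyModel):
    """Loop-decomposition energy of one structure (inf if not scorable)."""
    if not pairs:
        return 0.0
    pairs = sorted(pairs)
    children_of = {}
    top = []
    for (i, j) in pairs:
        parent = None
        for (a, b) in pairs:
            if a < i and j < b:
                if parent is None or (a > parent[0]):
                    parent = (a, b)
        if parent is None:
            top.append((i, j))
        else:
            children_of.setdefault(parent, []).append((i, j))

    total = 0.0
    for (i, j) in pairs:
        kids = sorted(children_of.get((i, j), []))
        if not kids:                                   # hairpin
            total += model.hairpin(j - i - 1)
        elif len(kids) == 1:
            (k, l) = kids[0]
            unpaired = (k - i - 1) + (j - l - 1)
            if unpaired == 0:                          # stack
                total += model.stack[(seq[i] + seq[j], seq[k] + seq[l])]
            elif unpaired <= model.max_interior:       # interior/bulge
                total += model.interior(unpaired)
            else:
                return float("inf")
        else:                                          # multiloop
            span = j - i - 1
            inside_branches = sum(b - a + 1 for (a, b) in kids)
            unpaired = span - inside_branches
            total += model.multi_base \
                + model.multi_branch * (len(kids) + 1) \
                + model.multi_unpaired * unpaired
    return total


def brute_force_mfe(seq, model: EnergyModel):
    """(energy, n_pairs) of the best enumerated structure (empty counts)."""
    best_e, best_pairs = 0.0, 0
    for pairs in enumerate_structures(seq):
        e = structure_energy(seq, pairs, model)
        if e < best_e:
            best_e, best_pairs = e, len(pairs)
    return best_e, best_pairs
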