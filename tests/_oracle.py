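"""Independent brute-force pathway enumerator used only as a test oracle.

Deliberately written with a different structure from the package engine:
an iterative worklist over explicit state tuples rather than recursion,
with the escalation rules re-derived inline from the raw integer
comparisons.  Pathways are returned as plain tuples so the comparison
with the package's output is purely structural.
"""

from math import comb


def _pmf(k: int, n: int, p: float) -> float:
    return comb(n, k) * p**k * (1 - p) ** (n - k)


def brute_force_pathways(A, B, C, D, E, deescalate, probs):
    """Return {cohort_seq: (probability, outcome)} for every possible trial.

    cohort_seq is a tuple of (dose, size, dlts); outcome is
    ("selected", j), ("none", None) or ("all_tolerated", None).
    """
    J = len(probs)
    done = {}
    # work items: (mode, dose, patients-per-dose, dlts-per-dose, cohorts, prob)
    work = [("first", 1, (0,) * J, (0,) * J, (), 1.0)]

    def bump(vec, j, amount):
        return vec[: j - 1] + (vec[j - 1] + amount,) + vec[j:]

    while work:
        mode, j, n, d, coh, pr = work.pop()
        if mode == "first":
            for x in range(A + 1):
                n2, d2 = bump(n, j, A), bump(d, j, x)
                c2 = coh + ((j, A, x),)
                p2 = pr * _pmf(x, A, probs[j - 1])
                if x < C:
                    if j == J:
                        done[c2] = (p2, ("all_tolerated", None))
                    else:
                        work.append(("first", j + 1, n2, d2, c2, p2))
                elif x <= D:
                    work.append(("second", j, n2, d2, c2, p2))
                else:
                    work.append(("stopped", j, n2, d2, c2, p2))
        elif mode == "second":
            for y in range(B + 1):
                n2, d2 = bump(n, j, B), bump(d, j, y)
                c2 = coh + ((j, B, y),)
                p2 = pr * _pmf(y, B, probs[j - 1])
                if d2[j - 1] <= E:
                    if j == J:
                        done[c2] = (p2, ("all_tolerated", None))
                    else:
                        work.append(("first", j + 1, n2, d2, c2, p2))
                else:
                    work.append(("stopped", j, n2, d2, c2, p2))
        elif mode == "stopped":
            if not deescalate:
                outcome = ("selected", j - 1) if j > 1 else ("none", None)
                done[coh] = (pr, outcome)
            else:
                work.append(("down", j - 1, n, d, coh, pr))
        else:  # mode == "down": de-escalation walk at dose j
            if j == 0:
                done[coh] = (pr, ("none", None))
            elif n[j - 1] >= A + B:
                if d[j - 1] <= E:
                    done[coh] = (pr, ("selected", j))
                else:
                    work.append(("down", j - 1, n, d, coh, pr))
            else:
                for y in range(B + 1):
                    n2, d2 = bump(n, j, B), bump(d, j, y)
                    c2 = coh + ((j, B, y),)
                    p2 = pr * _pmf(y, B, probs[j - 1])
                    if d2[j - 1] <= E:
                        done[c2] = (p2, ("selected", j))
                    else:
                        work.append(("down", j - 1, n2, d2, c2, p2))
    return done


def pathwayset_as_dict(ps):
    """Convert a package PathwaySet into the oracle's comparison form."""
    from abdesign import OutcomeKind

    out = {}
    for pw in ps:
        key = tuple((c.dose, c.size, c.dlts) for c in pw.cohorts)
        if pw.mtd.kind is OutcomeKind.SELECTED:
            outcome = ("selected", pw.mtd.dose)
        elif pw.mtd.kind is OutcomeKind.NONE_TOO_TOXIC:
            outcome = ("none", None)
        else:
            outcome = ("all_tolerated", None)
        out[key] = (pw.probability, outcome)
    return out
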