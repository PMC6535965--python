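"""Independent brute-force oracles used to cross-check the scanner.

Implemented by a different mechanism than the library (label strings and
explicit splitting rather than an index walk) so agreement is evidence, not
tautology.
"""

from __future__ import annotations


def brute_force_segments(code_wild, code_sport, min_run=5, max_gap=5, strict=False):
    """Enumerate qualifying LOH clusters directly from the definition.

    Returns a list of (first_index, last_index, n_discordant) tuples in
    original site indices.  Concordant-homozygous (and hom/hom mismatched)
    sites are uninformative and dropped; clusters split at any
    gain-of-heterozygosity site or at more than ``max_gap`` consecutive
    concordant-het sites; a cluster qualifies if it contains a run of at
    least ``min_run`` (strictly more when ``strict``) consecutive discordant
    sites.
    """
    labeled = []  # (orig_index, label)
    for i, (w, s) in enumerate(zip(code_wild, code_sport)):
        if w == 1 and s in (0, 2):
            labeled.append((i, "D"))
        elif w == 1 and s == 1:
            labeled.append((i, "H"))
        elif w in (0, 2) and s == 1:
            labeled.append((i, "R"))
        # else transparent

    # split into chunks at every R and at every run of >max_gap H
    chunks, cur, h_run = [], [], []
    for item in labeled:
        if item[1] == "R":
            chunks.append(cur)
            cur, h_run = [], []
        elif item[1] == "H":
            h_run.append(item)
            if len(h_run) > max_gap:
                chunks.append(cur)
                cur, h_run = [], []
        else:
            cur.extend(h_run)
            h_run = []
            cur.append(item)
    chunks.append(cur)

    need = min_run + 1 if strict else min_run
    out = []
    for chunk in chunks:
        d_items = [it for it in chunk if it[1] == "D"]
        if not d_items:
            continue
        # longest run of consecutive D within the chunk's label sequence
        best = run = 0
        for _, lab in chunk:
            run = run + 1 if lab == "D" else 0
            best = max(best, run)
        if best >= need:
            out.append((d_items[0][0], d_items[-1][0], len(d_items)))
    return out
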