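"""Brute-force reference implementation of the mismatch definitions.

Deliberately naive: explicit double loops over alleles and positions with no
shared code with :mod:`hlarepeat.mismatch`. Used for ground truth in the
synthetic-cohort generator and as the independent check in tests.
"""
from __future__ import annotations

from .mismatch import (CLASS_II_POOL, GROUP_LOCI, LOCUS_GROUPS, SPLIT_LOCI,
                       PositionResidue)
from .store import AlleleStore, UNKNOWN
from .subjects import HLATyping


def brute_split_mismatches(recipient: HLATyping, donor: HLATyping,
                           store: AlleleStore,
                           include_drb345: bool = False) -> dict[str, frozenset[str]]:
    def antigens(t: HLATyping, locus: str) -> set[str]:
        if locus == "DR":
            loci = ["DRB1"] + (["DRB3", "DRB4", "DRB5"] if include_drb345 else [])
        elif locus == "DQ":
            loci = ["DQB1"]
        else:
            loci = [locus]
        out = set()
        for lo in loci:
            for a in t.at(lo):
                if a.is_null:
                    continue
                out.add(store.split_antigen(a))
        return out

    result = {}
    for locus in SPLIT_LOCI:
        rec = antigens(recipient, locus)
        mm = set()
        for ag in antigens(donor, locus):
            if ag not in rec:
                mm.add(ag)
        result[locus] = frozenset(mm)
    return result


def brute_aa_mismatches(recipient: HLATyping, donor: HLATyping,
                        store: AlleleStore,
                        scope: str = "interlocus") -> dict[str, frozenset[PositionResidue]]:
    result = {}
    for group in LOCUS_GROUPS:
        pairs = set()
        for locus in GROUP_LOCI[group]:
            for da in donor.at(locus):
                if da.is_null:
                    continue
                if group == "class_I" or scope == "intralocus":
                    pool_loci = [locus]
                else:
                    pool_loci = list(CLASS_II_POOL)
                pool = []
                for lo in pool_loci:
                    for ra in recipient.at(lo):
                        if not ra.is_null:
                            pool.append(ra)
                for pos in sorted(store.mask.for_locus(locus)):
                    dres = store.residue_at(da, pos)
                    if dres == UNKNOWN:
                        continue
                    ok = True
                    for ra in pool:
                        if store.residue_at(ra, pos) == dres:
                            ok = False
                            break
                    if ok:
                        pairs.add(PositionResidue(group, pos, dres))
        result[group] = frozenset(pairs)
    return result


def brute_triad(recipient: HLATyping, kidney: HLATyping, msc: HLATyping,
                store: AlleleStore, scope: str = "interlocus",
                include_drb345: bool = False) -> dict:
    """Repeated mismatches by exhaustive double enumeration of both profiles."""
    ks = brute_split_mismatches(recipient, kidney, store, include_drb345)
    ms = brute_split_mismatches(recipient, msc, store, include_drb345)
    ka = brute_aa_mismatches(recipient, kidney, store, scope)
    ma = brute_aa_mismatches(recipient, msc, store, scope)
    rep_split = {}
    for locus in SPLIT_LOCI:
        shared = set()
        for a in ks[locus]:
            for b in ms[locus]:
                if a == b:
                    shared.add(a)
        rep_split[locus] = frozenset(shared)
    rep_aa = {}
    for g in LOCUS_GROUPS:
        shared = set()
        for p in ka[g]:
            for q in ma[g]:
                if p == q:
                    shared.add(p)
        rep_aa[g] = frozenset(shared)
    return {"kidney_split": ks, "msc_split": ms, "kidney_aa": ka, "msc_aa": ma,
            "repeated_split": rep_split, "repeated_aa": rep_aa}
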