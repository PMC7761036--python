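"""Independent brute-force re-implementation of the allocation rules.

Plain-dict arithmetic, no pandas, written directly from the rule text; used
only to cross-check the production allocator on small random profiles.
"""

from __future__ import annotations

from glycolinker.assignments import CLASS_ORDER, AssignmentTable


def oracle_allocate(
    amounts: dict[str, float],
    fraction_name: str | None,
    table: AssignmentTable,
) -> dict[str, dict[str, float]]:
    """linkage -> {class or "UA" -> allocated molar%}."""
    classes = {c: {str(lk) for lk in lks} for c, lks in table.classes.items()}
    order = [c for c in CLASS_ORDER if c in classes]
    suppressed = {
        (o["class"], o["linkage"])
        for o in table.overrides
        if fraction_name is not None and o["fraction"] == fraction_name
    }

    def cands(lk: str) -> list[str]:
        return [c for c in order if lk in classes[c] and (c, lk) not in suppressed]

    result = {lk: {c: 0.0 for c in order + ["UA"]} for lk in amounts}
    shared: list[str] = []

    # exclusive pass
    for lk, amt in amounts.items():
        cs = cands(lk)
        if not cs:
            result[lk]["UA"] = amt
        elif len(cs) == 1:
            result[lk][cs[0]] = amt
        else:
            shared.append(lk)

    # rule (a): 4-GalAp split by rhamnose backbone
    if "4-GalAp" in shared:
        cs = cands("4-GalAp")
        if "RG-I" in cs and "HG" in cs:
            amt = amounts["4-GalAp"]
            rha = amounts.get("2-Rhap", 0.0) + amounts.get("2,4-Rhap", 0.0)
            rg = min(amt, rha)
            result["4-GalAp"]["RG-I"] = rg
            result["4-GalAp"]["HG"] = amt - rg
            shared.remove("4-GalAp")

    # rule (b): 4-Glcp among XG / HM / CE
    if "4-Glcp" in shared:
        cs = cands("4-Glcp")
        if set(cs) <= {"XG", "HM", "CE"}:
            rem = amounts["4-Glcp"]
            if "XG" in cs:
                take = min(rem, amounts.get("4,6-Glcp", 0.0) * table.rules["xg_unbranched_ratio"])
                result["4-Glcp"]["XG"] = take
                rem -= take
            if "HM" in cs:
                take = min(rem, amounts.get("4-Manp", 0.0) * table.rules["glc_man_ratio"])
                result["4-Glcp"]["HM"] = take
                rem -= take
            for sink in ("CE", "XG", "HM"):
                if sink in cs:
                    result["4-Glcp"][sink] += rem
                    break
            shared.remove("4-Glcp")

    # rule (c): demand-proportional terminal splitting
    demand_sets = table.rules["demand_sets"]
    for lk in sorted(shared):
        cs = cands(lk)
        amt = amounts[lk]
        demands = []
        for c in cs:
            entry = demand_sets.get(c, {})
            dlks = entry.get(lk, entry.get("default", []))
            demands.append(
                sum(result.get(d, {}).get(c, 0.0) * w for d, w in dlks)
            )
        total = sum(demands)
        if total <= 0:
            result[lk][cs[0]] = amt
            continue
        acc = 0.0
        for c, d in zip(cs[:-1], demands[:-1]):
            share = amt * d / total
            result[lk][c] = share
            acc += share
        result[lk][cs[-1]] = amt - acc

    return result
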