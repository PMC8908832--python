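"""Area and gate geometry of the linear housing chain.

The housing system is a chain of four areas: the barn interior (IN), a
covered wintergarden (WG), a stone yard (SY) and the free-range pasture
(FR).  Hens move between adjacent areas only, through a single gate (pop
hole) per boundary.  Each gate carries one antenna on either side, so a
full passage produces two registrations: one on the exit side, one on the
entry side.
"""

from __future__ import annotations

#: Ordinal area codes; the chain is IN(1) - WG(2) - SY(3) - FR(4).
AREAS: tuple[str, ...] = ("IN", "WG", "SY", "FR")
AREA_CODE: dict[str, int] = {name: i + 1 for i, name in enumerate(AREAS)}
N_AREAS = len(AREAS)

#: Gates are indexed by the lower of the two areas they join:
#: gate g connects area g and area g+1 (1-based codes).
GATES: tuple[int, ...] = tuple(range(1, N_AREAS))


def gate_between(a: int, b: int) -> int:
    """Gate joining adjacent areas ``a`` and ``b`` (1-based codes)."""
    if abs(a - b) != 1:
        raise ValueError(f"areas {a} and {b} are not adjacent on the chain")
    return min(a, b)


def antenna_id(gate: int, side_area: int) -> str:
    """Antenna identifier, e.g. ``G1a`` = IN side of the IN/WG gate.

    Side ``a`` is the lower-numbered area of the gate, side ``b`` the
    higher-numbered one.
    """
    if side_area not in (gate, gate + 1):
        raise ValueError(f"area {side_area} does not border gate {gate}")
    return f"G{gate}{'a' if side_area == gate else 'b'}"


def default_gate_map() -> dict[str, dict]:
    """Antenna -> (gate, side area, area pair) mapping for the 4-area chain.

    This is the configuration shipped with the simulator; real
    installations provide the same structure as YAML.
    """
    gmap: dict[str, dict] = {}
    for g in GATES:
        for side in (g, g + 1):
            gmap[antenna_id(g, side)] = {
                "gate": g,
                "side_area": side,
                "areas": (g, g + 1),
            }
    return gmap


def chain_path(a: int, b: int) -> list[int]:
    """Unique path of areas from ``a`` to ``b`` along the chain, inclusive."""
    step = 1 if b >= a else -1
    return list(range(a, b + step, step))
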