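"""Eco-HAB habitat topology: compartments, tunnels, and RFID antennas.

The standard Eco-HAB arena is a ring of four large compartments joined by
four tube-shaped tunnels.  Each tunnel carries one RFID antenna at each end,
so a full tunnel traversal produces a pair of crossing events.  Food and
water are available ad libitum in two of the compartments (2 and 4 by
default), which is what the food-preference metric refers to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["HabitatTopology", "TopologyError"]


class TopologyError(ValueError):
    """Raised when an antenna/tunnel layout is internally inconsistent."""


@dataclass(frozen=True)
class HabitatTopology:
    """Map of compartments, tunnels and antennas.

    Parameters
    ----------
    compartments : tuple of int
        Compartment labels, canonically ``(1, 2, 3, 4)``.
    tunnels : tuple of (int, int)
        Unordered pairs of compartments joined by a tunnel.
    antennas : dict
        ``antenna_id -> (tunnel, end_compartment)`` where ``tunnel`` is the
        pair as stored in :attr:`tunnels` and ``end_compartment`` is the
        compartment adjacent to that antenna.
    food_compartments : frozenset of int
        Compartments containing food and water.
    """

    compartments: tuple[int, ...] = (1, 2, 3, 4)
    tunnels: tuple[tuple[int, int], ...] = ((1, 2), (2, 3), (3, 4), (4, 1))
    antennas: dict[str, tuple[tuple[int, int], int]] = field(default_factory=dict)
    food_compartments: frozenset[int] = frozenset({2, 4})

    def __post_init__(self) -> None:
        if not self.antennas:
            object.__setattr__(self, "antennas", self._default_antennas())
        self._validate()

    def _default_antennas(self) -> dict[str, tuple[tuple[int, int], int]]:
        ant: dict[str, tuple[tuple[int, int], int]] = {}
        k = 1
        for tun in self.tunnels:
            for end in tun:
                ant[str(k)] = (tun, end)
                k += 1
        return ant

    def _validate(self) -> None:
        comp = set(self.compartments)
        for tun in self.tunnels:
            if len(tun) != 2 or not set(tun) <= comp:
                raise TopologyError(f"bad tunnel {tun!r}")
        per_tunnel: dict[tuple[int, int], int] = {t: 0 for t in self.tunnels}
        for aid, (tun, end) in self.antennas.items():
            if tun not in per_tunnel:
                raise TopologyError(f"antenna {aid!r} references unknown tunnel {tun!r}")
            if end not in tun:
                raise TopologyError(
                    f"antenna {aid!r} end-compartment {end} not on tunnel {tun!r}"
                )
            per_tunnel[tun] += 1
        for tun, n in per_tunnel.items():
            if n != 2:
                raise TopologyError(f"tunnel {tun!r} has {n} antennas, expected 2")
        if not self.food_compartments <= comp:
            raise TopologyError("food_compartments must be a subset of compartments")

    # -- queries ---------------------------------------------------------

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def antenna_compartment(self, antenna_id: str) -> int:
        """Compartment adjacent to an antenna."""
        return self.antennas[antenna_id][1]

    def antenna_tunnel(self, antenna_id: str) -> tuple[int, int]:
        return self.antennas[antenna_id][0]

    def neighbors(self, compartment: int) -> tuple[int, ...]:
        """Compartments reachable from ``compartment`` through one tunnel."""
        out = []
        for a, b in self.tunnels:
            if a == compartment:
                out.append(b)
            elif b == compartment:
                out.append(a)
        return tuple(sorted(set(out)))

    def adjacent(self, a: int, b: int) -> bool:
        return a == b or b in self.neighbors(a)

    def tunnel_antennas(self, tunnel: tuple[int, int]) -> dict[int, str]:
        """``end_compartment -> antenna_id`` for one tunnel."""
        out = {}
        for aid, (tun, end) in self.antennas.items():
            if tun == tunnel:
                out[end] = aid
        return out

    # -- serialization ---------------------------------------------------

    @classmethod
    def default_ring(cls) -> "HabitatTopology":
        """The standard four-compartment ring with eight antennas."""
        return cls()

    @classmethod
    def from_yaml(cls, path) -> "HabitatTopology":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        tunnels = tuple(tuple(t) for t in doc["tunnels"])
        antennas = {
            str(aid): (tuple(spec["tunnel"]), int(spec["compartment"]))
            for aid, spec in doc.get("antennas", {}).items()
        }
        return cls(
            compartments=tuple(doc.get("compartments", (1, 2, 3, 4))),
            tunnels=tunnels,
            antennas=antennas,
            food_compartments=frozenset(doc.get("food_compartments", (2, 4))),
        )

    def to_yaml(self, path) -> None:
        doc = {
            "compartments": list(self.compartments),
            "tunnels": [list(t) for t in self.tunnels],
            "antennas": {
                aid: {"tunnel": list(tun), "compartment": end}
                for aid, (tun, end) in self.antennas.items()
            },
            "food_compartments": sorted(self.food_compartments),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
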