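"""Straight-line scalar reference implementation of the daily migration loop.

Written as plain per-agent / per-event Python loops, independent of the
vectorized engine, for use as a brute-force oracle on tiny worlds. Consumes
randomness in the same documented order as the engine (two uniform vectors
per day over all households, ascending household id) so results must agree
to floating-point exactness.
"""

from __future__ import annotations

import numpy as np


def scalar_haversine_km(lat1, lon1, lat2, lon2):
    r = 6371.0088
    p1, l1, p2, l2 = (np.radians(float(x)) for x in (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2
    return 2.0 * r * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def reference_simulation(persons, households, adjacency, events, params, horizon, seed):
    """Simulate with explicit loops; returns (records, history).

    ``records`` is a list of per-household dicts (household_id, day, type);
    ``history`` holds per-day per-household/person state dictionaries.
    """
    households = households.sort_values("household_id").reset_index(drop=True)
    persons = persons.sort_values(["household_id", "person_id"]).reset_index(drop=True)
    h_ids = [int(h) for h in households["household_id"]]
    n_h = len(h_ids)
    pos = {h: i for i, h in enumerate(h_ids)}

    members = {h: [] for h in h_ids}  # person rows in (household, person) order
    for row in persons.itertuples():
        members[int(row.household_id)].append(row)

    ev_rows = list(events.sort_values(["day", "event_id"]).itertuples())

    v_eff = params.v * params.b * params.w
    rng = np.random.default_rng(seed)

    active = {h: True for h in h_ids}
    f_tilde = {int(p.person_id): 0.0 for p in persons.itertuples()}
    records = []
    history = []

    def martial_idp(h):
        adults = [p for p in members[h] if p.age >= 18]
        return bool(adults) and all(p.gender == "male" and 18 <= p.age <= 60 for p in adults)

    for t in range(1, horizon + 1):
        hlat = {h: float(households.at[pos[h], "latitude"]) for h in h_ids}
        hlon = {h: float(households.at[pos[h], "longitude"]) for h in h_ids}

        f_house = {}
        for h in h_ids:
            total = 0.0
            for ev in ev_rows:
                dt = t - int(ev.day)
                if dt <= 0 or dt > params.event_horizon_days:
                    continue
                ds = max(scalar_haversine_km(hlat[h], hlon[h], ev.latitude, ev.longitude),
                         params.ds_floor_km)
                dtf = max(float(dt), params.dt_floor)
                fprime = float(ev.intensity) / (
                    np.exp(params.tau * np.log(dtf)) * np.exp(params.delta * np.log(ds))
                )
                if fprime < params.min_impact:
                    fprime = 0.0
                total = total + fprime
            f_house[h] = total

        p_prime = {}
        for h in h_ids:
            for p in members[h]:
                pid = int(p.person_id)
                if active[h]:
                    f_tilde[pid] = float(p.risk_proneness) * f_house[h] + params.theta * f_tilde[pid]
                p_prime[pid] = 1.0 / (1.0 + params.Q * np.exp(-v_eff * f_tilde[pid]))

        p_house = {}
        for h in h_ids:
            if not active[h]:
                p_house[h] = 0.0
                continue
            s = 0.0
            for p in members[h]:
                s += p_prime[int(p.person_id)]
            p_house[h] = s / float(len(members[h]))

        u_decision = rng.random(n_h)
        m_init = {h: bool(active[h] and u_decision[pos[h]] < p_house[h]) for h in h_ids}

        m_final = {}
        for h in h_ids:
            s = sum(1 for u in adjacency.get(h, ()) if m_init[int(u)])
            if s > params.i_hi:
                m = True
            elif s < params.i_lo:
                m = False
            else:
                m = m_init[h]
            m_final[h] = m and active[h]

        u_class = rng.random(n_h)
        newly = []
        for h in h_ids:
            if m_final[h]:
                if params.martial_law and martial_idp(h):
                    mtype = "idp"
                else:
                    mtype = "refugee" if u_class[pos[h]] < params.refugee_prob else "idp"
                records.append({"household_id": h, "day": t, "migration_type": mtype})
                newly.append(h)
                active[h] = False

        history.append(
            {
                "day": t,
                "f_house": np.array([f_house[h] for h in h_ids]),
                "f_tilde": np.array([f_tilde[int(p.person_id)] for p in persons.itertuples()]),
                "p_prime": np.array([p_prime[int(p.person_id)] for p in persons.itertuples()]),
                "p_house": np.array([p_house[h] for h in h_ids]),
                "m_initial": np.array([m_init[h] for h in h_ids]),
                "m_final": np.array([m_final[h] for h in h_ids]),
                "newly_migrated": np.array(newly, dtype=np.int64),
            }
        )

    return records, history
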