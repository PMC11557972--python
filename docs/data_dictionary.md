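# Data dictionary

## Observation table (`observations.csv`)

Long format, one row per scored (cage, hour) cell. Scoring convention: the
first five minutes of each hour are watched; a bee counts as sleeping when it
shows all three sleep markers (antennal immobility, non-continuously
pulsating abdomen, leg immobility) through the window, with a bee that is
jostled awake still counted as sleeping if it resumes sleep within 30 s.

| column                   | type | meaning |
|--------------------------|------|---------|
| `cage_id`                | str  | unique cage identifier (e.g. `LL2`) |
| `condition`              | enum | `LL` constant light, `DD` constant dark, `LD` 12 h light : 12 h dark control |
| `replicate_index`        | int  | 1-based replicate number within the condition |
| `hour`                   | int  | hours from experiment onset, 0-based, half-open `[0, duration)` |
| `n_alive`                | int  | bees alive at the start of the scored window |
| `n_sleeping`             | int  | bees asleep per the three-marker rule |
| `n_disturbance_contacts` | int  | total times sleeping bees were moved by contact with non-sleeping nestmates in the window |
| `n_sleeping_lower`       | int  | sleepers located in the lower 50% of the cage |

Invariants enforced on read: `0 <= n_sleeping <= n_alive`,
`0 <= n_sleeping_lower <= n_sleeping`, `n_alive` non-increasing in `hour`
within a cage, and a complete duplicate-free hour grid per cage starting at
hour 0.

## Light-measurement table (`light.csv`)

One row per photon-flux reading taken inside the cage.

| column        | type  | meaning |
|---------------|-------|---------|
| `position`    | enum  | `top` (sensor flush with the cage top) or `bottom` (sensor level with the cage floor) |
| `photon_flux` | float | photon flux in umol m^-2 s^-1, finite and non-negative |
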