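# screensim

Discrete-event simulation of a **high-end health-screening center**: six
customer types flow through 22 capacity-constrained examination stations
under first-in-first-out queueing, with fitted parametric service-time
laws, clinical sequencing constraints (fasting examinations before lunch,
anesthesia recovery immediately after endoscopy), and time-varying room
capacities (shared rooms switch function at noon).

The package is aimed at health-services and operations researchers who
want to quantify **per-customer waiting time**, identify **bottleneck
stations**, and compare **process-improvement policies** — rebalancing the
customer-type mix, adding capacity at the bottleneck, or replacing free
check-in with scheduled batch arrivals — for a screening clinic whose
day is a *terminating* system (opens 7:00 AM, drains by late afternoon),
analyzed over independent replications.

## Model in brief

* **Entities.** Customers of six types (X1–X3 female, Y1–Y3 male, observed
  shares 10.93/29.89/1.58/20.11/34.03/3.46 %), each following a fixed
  ordered route of stations coded `A`–`V` (check-in to exit).
* **Service times.** Per-station laws in the Arena parameter convention:
  offset + UNIF(a,b) / ERLA(1/λ,k) / EXPO(1/λ) / LOGN(μ,σ) / β·BETA(β,α) /
  GAMM(1/λ,α), where the lognormal is specified by its *arithmetic* mean
  and sd.  Closed-form moments, seeded sampling, and maximum-likelihood
  fitting with KS-based family selection are provided.
* **Queueing.** One FIFO queue per station; capacity is a schedule of
  half-open windows (e.g. height/weight runs mornings only); capacity
  drops are non-preemptive.  An event-calendar engine processes events in
  `(time, sequence)` order, so a run is bit-reproducible from its seed.
* **Arrivals.** Empirical check-in histogram (1.4 % before opening, 52.2 %
  in 7–8 AM, 37.4 % in 8–9 AM, rest to 9:30) or deterministic batch
  schedules.
* **Output analysis.** Per-type waiting/total times and throughput,
  per-station mean queue wait, time-average queue length and utilization,
  averaged over R independent replications (default 50); stations whose
  mean queue wait exceeds 5 min are flagged as bottlenecks; observed
  service-time statistics are validated with normal-theory 95 % intervals
  `mean ± 1.96·sd/√n`.
* **Synthetic data.** A generator emulates RFID-wristband visit logs
  (entry/exit per station, missing-sensor events, inflated outliers) and a
  three-rule cleaner (unknown type → missing timestamp → duration > 2× the
  station mean) feeds the fitting stage, so the whole pipeline is testable
  without field data.

See [docs/methods.md](docs/methods.md) for assumptions, calibration
choices and limitations.

## Worked example

Simulate the baseline day (30 customers, 50 replications) and compare the
three improvement policies:

```bash
screensim simulate --volume 30 --reps 50 --seed 12345 --outdir out
screensim compare-policies --volume 30 --reps 50 --seed 12345 --outdir out
```

prints

```
INFO screensim: baseline: mean waiting 59.15 min, total 197.17 min, bottlenecks ['L', 'H', 'O']
INFO screensim: baseline     waiting 59.15 total 197.17
INFO screensim: S1_mix       waiting 66.44 total 212.87
INFO screensim: S2_capacity  waiting 46.40 total 183.98
INFO screensim: S3_schedule  waiting 52.06 total 189.77
```

Reading: an average customer spends about 59 min of a 197-min visit
waiting; the gastrointestinal endoscopy `L` is the dominant bottleneck
(mean queue wait ≈ 30 min, see `out/summary_by_station.csv`).  Booking a
uniform customer-type mix (S1) *worsens* waiting — it multiplies the rare
types whose routes include the single-slot coronary CT — while adding one
endoscopy team (S2) and batch-scheduling arrivals (S3, batches of 5 every
25 min) both reduce it, S2 most strongly.  `out/summary_by_type.csv`
breaks the same run down by customer type, e.g.

```
type,number_out,waiting_time_min,total_time_min
X1,2.56,63.18,206.06
X2,9.24,54.38,197.28
...
```

The full synthetic pipeline (generate wristband logs → clean → fit →
simulate → validate against observed station statistics):

```bash
screensim pipeline --n-customers 2000 --volume 30 --reps 50 --seed 42 --outdir out
```

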