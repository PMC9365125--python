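"""Threshold-based genus/species delineation with rule tracing.

The decision system applies the published genomic thresholds to pairwise
relatedness metrics:

* 16S rRNA similarity 98.7% — species boundary (non-decisive on its own:
  a 16S value above it only means the species cannot be excluded by 16S);
* ANI 95% and dDDH 70% — species boundary (OR rule, conflicts flagged);
* AAI 95–96% — species band; AAI 65–66% — genus band.  Band thresholds are
  intervals with "borderline" as an explicit output state rather than a
  forced binary call.

Every verdict carries the ordered list of applied rules, so a call is a
pure function of its metric inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import GenotaxError


@dataclass(frozen=True)
class Thresholds:
    s16_species: float = 98.7
    ani_species: float = 95.0
    ddh_species: float = 70.0
    aai_species_low: float = 95.0
    aai_species_high: float = 96.0
    aai_genus_low: float = 65.0
    aai_genus_high: float = 66.0
    #: values in (high, high+margin] are still "borderline", not same-genus
    #: evidence — reported genus boundaries span roughly 64-67% depending on
    #: the study, so a value just above the nominal band is not treated as
    #: positive placement evidence.
    aai_genus_margin: float = 1.5

    def __post_init__(self):
        vals = [
            self.s16_species, self.ani_species, self.ddh_species,
            self.aai_species_low, self.aai_species_high,
            self.aai_genus_low, self.aai_genus_high,
        ]
        if not all(0 < v < 100 for v in vals):
            raise GenotaxError("thresholds must lie in (0, 100)")
        if self.aai_species_low > self.aai_species_high or self.aai_genus_low > self.aai_genus_high:
            raise GenotaxError("band low must not exceed band high")


@dataclass
class RuleEval:
    metric: str
    value: float
    threshold: str
    outcome: str


@dataclass
class PairCall:
    reference: str
    species_call: str           # same | distinct | undetermined
    genus_call: str             # same | borderline | distinct | undetermined
    species_conflict: bool
    s16_note: str
    evaluations: list[RuleEval] = field(default_factory=list)


@dataclass
class TaxonomicVerdict:
    query_id: str
    per_reference: dict[str, PairCall]
    species_overall: str        # "novel species" | "conspecific with <ref>" | ...
    genus_placement: str        # clade label | "novel genus candidate" | "conflict" | "undetermined"
    overall: str
    trace: list[str] = field(default_factory=list)


def classify_pair(
    metrics: dict[str, float], reference: str = "reference", thresholds: Thresholds = Thresholds()
) -> PairCall:
    """Species/genus calls for one query-reference pair.

    ``metrics`` maps metric names (ANI, dDDH, AAI, 16S) to percentages; at
    least one of ANI/dDDH must be present.
    """
    known = {k for k in metrics if k in ("ANI", "dDDH", "AAI", "16S")}
    if not ({"ANI", "dDDH"} & known):
        raise GenotaxError("classify_pair needs ANI and/or dDDH")
    evals: list[RuleEval] = []
    votes = []
    if "ANI" in metrics:
        same = metrics["ANI"] >= thresholds.ani_species
        votes.append(same)
        evals.append(RuleEval("ANI", metrics["ANI"], f">= {thresholds.ani_species}", "same-species" if same else "distinct"))
    if "dDDH" in metrics:
        same = metrics["dDDH"] >= thresholds.ddh_species
        votes.append(same)
        evals.append(RuleEval("dDDH", metrics["dDDH"], f">= {thresholds.ddh_species}", "same-species" if same else "distinct"))
    species_call = "same" if any(votes) else "distinct"
    conflict = len(set(votes)) > 1

    genus_call = "undetermined"
    if "AAI" in metrics:
        aai = metrics["AAI"]
        if aai > thresholds.aai_genus_high + thresholds.aai_genus_margin:
            genus_call = "same"
        elif aai < thresholds.aai_genus_low:
            genus_call = "distinct"
        else:
            genus_call = "borderline"
        evals.append(
            RuleEval(
                "AAI",
                aai,
                f"band [{thresholds.aai_genus_low}, {thresholds.aai_genus_high}] "
                f"(+{thresholds.aai_genus_margin} margin)",
                f"{genus_call}-genus",
            )
        )
    s16_note = ""
    if "16S" in metrics:
        if metrics["16S"] >= thresholds.s16_species:
            s16_note = "16S above species boundary: species cannot be excluded by 16S alone"
            outcome = "non-decisive (above boundary)"
        else:
            outcome = "below species boundary"
        evals.append(RuleEval("16S", metrics["16S"], f">= {thresholds.s16_species}", outcome))
    return PairCall(
        reference=reference,
        species_call=species_call,
        genus_call=genus_call,
        species_conflict=conflict,
        s16_note=s16_note,
        evaluations=evals,
    )


def classify_strain(
    query_id: str,
    reference_metrics: dict[str, dict[str, float]],
    clade_map: dict[str, str],
    thresholds: Thresholds = Thresholds(),
) -> TaxonomicVerdict:
    """Full verdict for a query against a reference panel.

    ``reference_metrics``: reference id -> {metric: value}.  ``clade_map``
    assigns each reference to a clade label (genus hypothesis).
    """
    if not reference_metrics:
        raise GenotaxError("classify_strain needs at least one reference")
    per_ref = {}
    trace = []
    for ref, metrics in reference_metrics.items():
        call = classify_pair(metrics, reference=ref, thresholds=thresholds)
        per_ref[ref] = call
        for ev in call.evaluations:
            trace.append(f"{ref}: {ev.metric}={ev.value} ({ev.threshold}) -> {ev.outcome}")
        if call.species_conflict:
            trace.append(f"{ref}: ANI and dDDH disagree on the species call")

    conspecific = [r for r, c in per_ref.items() if c.species_call == "same"]
    if conspecific:
        species_overall = f"conspecific with {sorted(conspecific)[0]}"
    else:
        species_overall = "novel species"
    trace.append(f"species: {species_overall}")

    # genus placement from clade-level AAI evidence
    clades = sorted(set(clade_map.values()))
    clade_calls: dict[str, str] = {}
    for clade in clades:
        refs = [r for r in per_ref if clade_map.get(r) == clade]
        calls = {per_ref[r].genus_call for r in refs} - {"undetermined"}
        if not calls:
            clade_calls[clade] = "undetermined"
        elif calls == {"same"}:
            clade_calls[clade] = "same"
        elif "same" in calls:
            clade_calls[clade] = "conflict"
        elif calls == {"distinct"}:
            clade_calls[clade] = "distinct"
        else:
            clade_calls[clade] = "borderline-or-distinct"
        trace.append(f"genus evidence vs clade {clade}: {clade_calls[clade]}")

    same_clades = [c for c, v in clade_calls.items() if v == "same"]
    if any(v == "conflict" for v in clade_calls.values()):
        genus_placement = "conflict"
        overall = "conflict: inconsistent genus evidence within a clade"
    elif len(same_clades) == 1:
        genus_placement = same_clades[0]
        overall = f"{species_overall}, genus {genus_placement}"
    elif len(same_clades) > 1:
        genus_placement = "conflict"
        overall = "conflict: same-genus evidence with multiple clades"
    elif all(v in ("distinct", "borderline-or-distinct", "undetermined") for v in clade_calls.values()):
        genus_placement = "novel genus candidate"
        overall = f"{species_overall}, novel genus candidate"
    else:
        genus_placement = "undetermined"
        overall = species_overall
    trace.append(f"genus placement: {genus_placement}")
    if not conspecific:
        trace.append(f"overall: {overall}")
    return TaxonomicVerdict(
        query_id=query_id,
        per_reference=per_ref,
        species_overall=species_overall,
        genus_placement=genus_placement,
        overall=overall,
        trace=trace,
    )


def load_metrics_tsv(path) -> dict[str, dict[str, float]]:
    """Read the long-format metric TSV (genome_a, genome_b, metric, value)
    into {reference: {metric: value}} for the single query it contains."""
    out: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if cells[0] == "genome_a":
                continue
            _, ref, metric, value = cells[:4]
            out.setdefault(ref, {})[metric] = float(value)
    if not out:
        raise GenotaxError(f"{path}: no metric rows")
    return out


def load_clade_map(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if cells[0] == "genome_id":
                continue
            out[cells[0]] = cells[1]
    return out
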