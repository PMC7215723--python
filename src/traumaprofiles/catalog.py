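"""Built-in catalog of the war-problems questionnaire instrument.

The instrument covers 106 binary trauma/stressor items -- 22 traumatic
experiences plus 84 war-related general problems (family, economic, social,
lack of basic needs, physical) -- and Likert-rated symptom subscales for
anxiety and depression (1 = not at all ... 4 = extremely). Each entry below
carries the marginal prevalence (percent of n = 337 respondents endorsing
the item) observed in the Sri Lankan civil-war survivor sample the
instrument was fielded in; the synthetic generator uses these as its
default marginals.
"""

from __future__ import annotations

from .schema import ItemDefinition, OutcomeSpec, Schema

#: (item_id, label, section, prevalence %) for the 106 binary items.
ITEM_TABLE: tuple[tuple[str, str, str, float], ...] = (
    ("witnessed_injury", "Witnessed the injury of loved ones", "trauma", 47.5),
    ("witnessed_death", "Witnessed the death of loved ones", "trauma", 44.5),
    ("beaten_detention", "Beaten in detention", "trauma", 36.5),
    ("been_imprisoned", "Been imprisoned", "trauma", 35.9),
    ("other_family_kidnapped", "Family members (besides spouse, children, parents) been kidnapped", "trauma", 17.5),
    ("injured_airstrikes_bomb_explosions", "Injured by airstrikes or bomb explosions or sudden attacks", "trauma", 15.4),
    ("been_kidnapped", "Been kidnapped", "trauma", 12.5),
    ("tortured_petrol_bag", "Tortured by being beaten with a bag containing petrol", "trauma", 11.9),
    ("children_kidnapped", "Children been kidnapped", "trauma", 11.6),
    ("death_child_children_war", "Death of child/children in war", "trauma", 11.3),
    ("death_spouse_war", "Death of spouse in war", "trauma", 9.2),
    ("children_handicapped", "Children been handicapped", "trauma", 9.2),
    ("tortured_nail_pin", "Tortured by being pricked under the nail with a pin", "trauma", 9.2),
    ("death_mother_father_war", "Death of mother and/or father in war", "trauma", 8.9),
    ("tortured_cigarette_burn", "Tortured by being burnt with a cigarette butt in detention", "trauma", 8.6),
    ("electrocuted_detention", "Electrocuted in detention", "trauma", 7.7),
    ("husband_wife_kidnapped", "Husband or wife been kidnapped", "trauma", 7.7),
    ("husband_wife_handicapped", "Husband or wife been handicapped", "trauma", 5.6),
    ("tortured_mosquito_coil", "Tortured by being forcibly fed mosquito coil", "trauma", 4.2),
    ("caught_land_mine", "Caught in a land mine", "trauma", 3.3),
    ("parents_kidnapped", "Parent(s) been kidnapped", "trauma", 2.4),
    ("been_raped", "Been raped", "trauma", 1.2),
    ("insufficient_support_relatives", "Insufficient support from relatives", "family", 48.7),
    ("children_spouse_psychological_problems", "Children/spouse has psychological problems", "family", 47.2),
    ("no_steady_life_family_duties", "No steady life because of duties towards family", "family", 46.6),
    ("unable_take_care_children", "Unable to take care of children", "family", 36.2),
    ("separated_from_family", "Having been separated from husband/wife/children/other relatives", "family", 28.5),
    ("unable_get_children_married", "Unable to get children married/give dowry", "family", 26.7),
    ("travel_restrictions_relatives", "Not being able to travel to meet relatives due to travel restrictions", "family", 26.4),
    ("no_old_age_caretaker", "Not having anyone to take care of you in old age", "family", 23.7),
    ("dependent_relatives", "Being dependent on relatives", "family", 22.6),
    ("problems_husband_wife_home", "Problems with husband/wife at home", "family", 22.6),
    ("single_caretaker_children_siblings", "Taking care of your children and siblings as a single person", "family", 20.5),
    ("problems_between_children", "Problems between children", "family", 20.2),
    ("unable_discipline_children", "Unable to control (i.e., discipline) your children", "family", 18.4),
    ("problems_marriage_plans", "Problems with marriage plans", "family", 11.0),
    ("alcohol_abuse_self", "Alcohol abuse by self", "family", 9.2),
    ("alcohol_abuse_husband_wife", "Alcohol abuse by husband or wife", "family", 7.4),
    ("no_children_though_wanted", "Not having any children though you wanted them", "family", 7.4),
    ("dependent_wife", "Being dependent on wife", "family", 7.4),
    ("alcohol_abuse_parents", "Alcohol abuse by parents", "family", 4.2),
    ("not_cared_for_by_children", "Not being properly looked after or cared for by children", "family", 0.6),
    ("cannot_earn_enough", "Not being able to earn enough money for your basic needs", "economic", 89.3),
    ("no_money", "Not having money", "economic", 86.1),
    ("loss_material_goods", "Loss of material goods", "economic", 84.9),
    ("unavailability_employment", "Unavailability of employment", "economic", 83.1),
    ("cannot_work_illness", "Not being able to work due to illness", "economic", 83.1),
    ("financial_debt", "Financial debt", "economic", 82.8),
    ("cannot_do_desired_job", "Not being able to do the job you desire", "economic", 81.0),
    ("loss_house_land", "Loss of house/land", "economic", 77.2),
    ("loss_work_equipment", "Loss of work equipment", "economic", 73.0),
    ("cannot_work_single_parent", "Not being able to work due to being a single parent", "economic", 52.2),
    ("fear_of_death", "Fear of death (from bombs/land mines/armed groups)", "social", 65.6),
    ("problems_travel", "Problems with travel", "social", 57.0),
    ("stress_moving_new_place", "Stress when moving to a new place", "social", 51.3),
    ("no_usual_routines_after_move", "Not being able to do usual routines after having moved to a new place", "social", 49.9),
    ("fear_being_kidnapped", "Fear of being kidnapped", "social", 49.3),
    ("cannot_talk_freely", "Not being able to talk freely", "social", 46.0),
    ("no_official_documents", "Not having official documents", "social", 33.5),
    ("losing_community", "Losing one's community", "social", 30.0),
    ("living_relatives", "Living with relatives", "social", 25.5),
    ("unable_participate_cultural_events", "Unable to participate in cultural events", "social", 21.1),
    ("living_alone_without_anyone", "Living alone (without anyone)", "social", 20.8),
    ("bribes_for_services", "Having to give bribes to get basic services", "social", 16.9),
    ("not_respected_society", "Not being respected by society", "social", 16.6),
    ("lack_security_being_alone", "Lack of security due to being alone", "social", 16.3),
    ("staying_away_from_relatives", "Staying away from relatives so not to disgrace them", "social", 16.3),
    ("isolated_society_unemployment", "Isolated in society due to unemployment", "social", 13.1),
    ("victim_theft", "Been a victim of theft", "social", 12.2),
    ("isolated_society_history_imprisoned", "Isolated in society due to history of being imprisoned", "social", 11.9),
    ("living_camp", "Living in a camp", "social", 11.0),
    ("neglected_society", "Neglected by society", "social", 10.7),
    ("living_non_relatives", "Living with non-relatives", "social", 9.8),
    ("cannot_get_married", "Not being able to get married", "social", 7.4),
    ("isolated_society_widow", "Isolated from society due to being a widow", "social", 7.1),
    ("problems_neighbors_others_camp", "Problems with neighbors or others in the camp", "social", 6.2),
    ("fear_sexual_abuse_widow", "Fear of sexual abuse due to being a widow", "social", 5.9),
    ("unable_get_married_stigma", "Unable to get married due to stigma", "social", 3.3),
    ("lack_proper_security", "Lack of proper security", "basic_needs", 62.3),
    ("losing_rights", "Losing your rights", "basic_needs", 59.9),
    ("lack_medical_facilities", "Lack of medical facilities", "basic_needs", 59.9),
    ("lack_food", "Lack of food", "basic_needs", 54.9),
    ("lack_clothes", "Lack of clothes", "basic_needs", 53.4),
    ("lack_fuel", "Lack of fuel", "basic_needs", 49.0),
    ("cannot_obtain_education", "Not being able to obtain education", "basic_needs", 40.1),
    ("lack_water", "Lack of water", "basic_needs", 34.4),
    ("problems_keeping_clean", "Problems keeping clean", "basic_needs", 30.9),
    ("body_aches", "Body aches", "physical", 62.6),
    ("headaches", "Headaches", "physical", 64.4),
    ("backache", "Backache", "physical", 57.9),
    ("shivering", "Shivering", "physical", 41.8),
    ("eye_problems", "Eye problems", "physical", 33.5),
    ("high_blood_pressure", "High blood pressure", "physical", 22.0),
    ("problems_using_hands_legs", "Problems using hands or legs", "physical", 21.1),
    ("loss_teeth", "Loss of teeth", "physical", 17.8),
    ("cannot_walk_with_both_legs", "Not being able to walk even with having both legs", "physical", 16.0),
    ("heart_problems", "Heart problems", "physical", 15.7),
    ("burns_boils", "Burns/boils", "physical", 15.4),
    ("fractures", "Fractures", "physical", 14.8),
    ("deaf", "Deaf", "physical", 10.1),
    ("head_injury", "Head injury", "physical", 10.1),
    ("retention_bullet_bomb_particles", "Retention of bullet or bomb particles in the body", "physical", 9.5),
    ("loss_arms_legs_landmine", "Loss of arms or legs in a landmine", "physical", 6.2),
    ("kidney_problems", "Kidney problems", "physical", 7.1),
    ("stroke_blood_clots", "Stroke/blood clots", "physical", 6.8),
    ("loss_arms_legs_child", "Loss of arms or legs of a child or spouse or breadwinner due to a landmine", "physical", 4.2),
)

#: Observed prevalence (%) of the four binary psychopathology indicators.
OUTCOME_PREVALENCES: dict[str, float] = {
    "some_anxiety": 67.1,
    "severe_anxiety": 21.4,
    "some_depression": 63.8,
    "severe_depression": 15.1,
}

#: Study sample size the catalog prevalences refer to.
STUDY_N = 337

#: Default number of Likert items per synthetic symptom subscale. The
#: instrument's exact subscale lengths are not part of this catalog; five
#: items is a typical short-subscale length and is what the generator uses.
DEFAULT_SUBSCALE_K = 5

SUBSCALES: tuple[tuple[str, float, float], ...] = (
    # (subscale name, "some" prevalence % at threshold 2.0, "severe" % at 3.0)
    ("anxiety", 67.1, 21.4),
    ("depression", 63.8, 15.1),
)


def catalog_items() -> tuple[ItemDefinition, ...]:
    """The 106 binary items as antecedent :class:`ItemDefinition` objects."""
    return tuple(
        ItemDefinition(item_id=i, label=lab, role="antecedent", section=sec)
        for i, lab, sec, _ in ITEM_TABLE
    )


def catalog_prevalences() -> dict[str, float]:
    """item_id -> marginal prevalence as a probability in [0, 1]."""
    return {i: pct / 100.0 for i, _, _, pct in ITEM_TABLE}


def default_schema(k: int = DEFAULT_SUBSCALE_K) -> Schema:
    """Schema matching datasets produced by the default synthetic profile.

    Each symptom subscale contributes ``k`` Likert columns named
    ``<name>_1 .. <name>_k`` and two outcomes (mean >= 2.0 -> ``some_<name>``,
    mean >= 3.0 -> ``severe_<name>``).
    """
    likert_ids: list[str] = []
    outcomes: list[OutcomeSpec] = []
    for name, _some, _severe in SUBSCALES:
        cols = tuple(f"{name}_{j + 1}" for j in range(k))
        likert_ids.extend(cols)
        outcomes.append(
            OutcomeSpec(
                outcome_id=f"some_{name}",
                subscale_item_ids=cols,
                mean_threshold=2.0,
                label=f"Some {name}",
            )
        )
        outcomes.append(
            OutcomeSpec(
                outcome_id=f"severe_{name}",
                subscale_item_ids=cols,
                mean_threshold=3.0,
                label=f"Severe {name}",
            )
        )
    return Schema(
        items=catalog_items(),
        likert_item_ids=tuple(likert_ids),
        outcomes=tuple(outcomes),
    )


def item_label(item_id: str) -> str:
    """Questionnaire text for a catalog item id (falls back to the id)."""
    for i, lab, _, _ in ITEM_TABLE:
        if i == item_id:
            return lab
    return item_id
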