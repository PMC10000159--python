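# Modified wolf ethogram: behaviour codes grouped into 11 behavioural
# categories. Bold additions of the source taxonomy (Forage, Run, Object
# Interaction, Group Formation, Leave Together, and the whole submissive
# category) are included because the default social-reward chain needs them.
#
# Editorial note: a few behaviours (Approach, Follow, Airplane Ears, Lick)
# appear under several categories in the original two-level taxonomy; a code
# must belong to exactly one category here, so each such behaviour is
# assigned to the category of its first listing.
version_label: goodmann2002_modified
categories:
  agonistic:
    - {code: ElicAggr, label: Elicited Aggression}
    - {code: FoodAggr, label: Food-related Aggression}
    - {code: SexAggr, label: Sex-related Aggression}
    - {code: AllOutAtk, label: All-Out Attack}
    - {code: DefSubm, label: Defence and Submission}
    - {code: OffThreat, label: Offensive Threat}
    - {code: RitAtk, label: Ritualised Attack}
    - {code: CntrAtk, label: Counterattack}
    - {code: Fight, label: Fight}
  play:
    - {code: AgonPlay, label: Agonistic Play}
    - {code: SocPlay, label: Social Play}
    - {code: SolPlay, label: Solitary Play}
  caregiving:
    - {code: Apprch, label: Approach}
    - {code: Sniffle, label: Sniffle}
    - {code: FaceWipe, label: Face Wipe}
    - {code: Follow, label: Follow}
    - {code: HoldFace, label: Hold Out Face}
    - {code: AirplEars, label: Airplane Ears}
  submissive:
    - {code: ExpBelly, label: Expose Belly}
    - {code: DownLick, label: Down and Lick}
    - {code: LickSn, label: Lick Snout}
    - {code: LowPost, label: Low Posture}
    - {code: C.SubmBhv, label: Combined submissive behaviours}
  feeding:
    - {code: Cache, label: Cache}
    - {code: CarryObj, label: Carry Object}
    - {code: Drag, label: Drag}
    - {code: Eat, label: Eat}
    - {code: Forage, label: Forage}
    - {code: Grab, label: Grab}
    - {code: Lick, label: Lick}
    - {code: Mouth, label: Mouth}
    - {code: Paw, label: Paw}
    - {code: Tug, label: Tug}
  greeting:
    - {code: BodyRub, label: Body Rub}
    - {code: EarsBack, label: Ears Back}
    - {code: EarsPrick, label: Ears Pricked}
    - {code: Greet, label: Greet}
    - {code: GrpFrmt, label: Group Formation/Group Together}
    - {code: Grin, label: Grin}
    - {code: Hug, label: Hug}
    - {code: Hum, label: Hum}
    - {code: LeaveTgh, label: Leave Together}
    - {code: ParGait, label: Parallel Gait}
    - {code: ParWalk, label: Parallel Walk}
    - {code: SniffNose, label: Sniff Noses}
    - {code: TailWag, label: Tail Wag}
  locomotion/exploratory:
    - {code: Amble, label: Amble}
    - {code: Avoid, label: Avoid}
    - {code: Observ, label: Observation}
    - {code: Nobj, label: Object Interaction}
    - {code: ObsJump, label: Observation Jump}
    - {code: Run, label: Run}
  scent-marking:
    - {code: ScentMark, label: Scent-Marking}
    - {code: Elim, label: Elimination}
  other:
    - {code: Explore, label: Explore}
    - {code: IndApprch, label: Indirect Approach}
    - {code: Orient, label: Orient}
    - {code: Wander, label: Wander}
  predation:
    - {code: Hunt, label: Hunting}
  resting:
    - {code: Rest, label: Resting}
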