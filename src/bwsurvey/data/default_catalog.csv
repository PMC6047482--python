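item_id,label,kind
pain_relief,Pain relief,benefit
normal_activities,Improvement in your ability to do normal activities,benefit
sleep,Improvement in sleep,benefit
quality_of_life,Changes in the overall quality of your life,benefit
mood,Changes in mood,benefit
less_other_meds,Reduction in the need for other pain medication,benefit
side_effects,Side effects (all potential harms considered together),side_effects_aggregate
death,Death,harm
fainting,Fainting,harm
headache,Headache,harm
dizziness,Dizziness,harm
nausea_vomiting,Nausea or vomiting,harm
memory_problems,Memory problems,harm
confusion,Confusion or trouble concentrating,harm
mood_changes,Mood changes (e.g. depression or anxiety),harm
suicidal_thoughts,Suicidal thoughts,harm
weight_change,Weight gain or weight loss,harm
fatigue,Fatigue or drowsiness,harm
sleep_problems,Sleep problems,harm
skin_problems,"Skin problems (e.g. dry skin, acne, rash)",harm
vision_problems,Vision problems,harm
liver_problems,Liver problems,harm
heart_problems,Heart or circulation problems,harm
breathing_problems,Breathing problems,harm
digestive_problems,"Digestive problems (e.g. constipation, diarrhea)",harm
sexual_problems,Sexual problems,harm
dependence,Dependence or withdrawal symptoms,harm
tremor,Tremor or muscle twitching,harm
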