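criterion_id,name,domain_tag,level_rank,level_label
patient_needs,Patient needs and resources,Outer Setting,0,Does not address patient needs
patient_needs,Patient needs and resources,Outer Setting,1,Moderately addresses patient needs
patient_needs,Patient needs and resources,Outer Setting,2,Highly addresses patient needs
cost,Cost to implement,Intervention Characteristics,0,Expensive
cost,Cost to implement,Intervention Characteristics,1,Neither expensive nor cheap
cost,Cost to implement,Intervention Characteristics,2,Cheap
adaptability,Adaptability to meet local needs,Intervention Characteristics,0,Less adaptable
adaptability,Adaptability to meet local needs,Intervention Characteristics,1,Moderately adaptable
adaptability,Adaptability to meet local needs,Intervention Characteristics,2,Highly adaptable
priority,Relative priority of implementing intervention,Inner Setting,0,Low priority
priority,Relative priority of implementing intervention,Inner Setting,1,Medium priority
priority,Relative priority of implementing intervention,Inner Setting,2,High priority
advantage,Relative advantage of implementing intervention,Intervention Characteristics,0,Low advantage
advantage,Relative advantage of implementing intervention,Intervention Characteristics,1,Medium advantage
advantage,Relative advantage of implementing intervention,Intervention Characteristics,2,High advantage
resources,Available resources for implementation,Inner Setting,0,Less available
resources,Available resources for implementation,Inner Setting,1,Moderately available
resources,Available resources for implementation,Inner Setting,2,Highly available
evidence,Evidence about the intervention's impact,Intervention Characteristics,0,Low evidence
evidence,Evidence about the intervention's impact,Intervention Characteristics,1,Moderate evidence
evidence,Evidence about the intervention's impact,Intervention Characteristics,2,Strong evidence
knowledge,Knowledge and beliefs about intervention,Characteristics of Individuals,0,Negative attitude
knowledge,Knowledge and beliefs about intervention,Characteristics of Individuals,1,Neither positive nor negative attitude
knowledge,Knowledge and beliefs about intervention,Characteristics of Individuals,2,Positive attitude
identification,Identification with organisation,Characteristics of Individuals,0,Not well known in the organisation
identification,Identification with organisation,Characteristics of Individuals,1,Moderately known in the organisation
identification,Identification with organisation,Characteristics of Individuals,2,Highly known in the organisation
planning,Planning to facilitate the intervention implementation,Implementation Process,0,Not well planned
planning,Planning to facilitate the intervention implementation,Implementation Process,1,Moderately planned
planning,Planning to facilitate the intervention implementation,Implementation Process,2,Well planned
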