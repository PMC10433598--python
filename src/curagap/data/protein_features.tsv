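residue	feature
5	phosphorylation
11	phosphorylation
12	phosphorylation
14	phosphorylation
68	creatine_binding
72	creatine_binding
73	creatine_binding
132	helix_stabilizing
144	creatine_binding
148	helix_stabilizing
171	glycosylation
172	disulfide
175	glycosylation
178	glycosylation
181	disulfide
192	glycosylation
197	glycosylation
286	leucine_zipper
293	leucine_zipper
300	leucine_zipper
314	creatine_binding
315	creatine_binding
318	creatine_binding
321	creatine_binding
382	creatine_binding
417	creatine_binding
421	creatine_binding
548	glycosylation
618	phosphorylation
620	phosphorylation
623	phosphorylation
625	phosphorylation
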