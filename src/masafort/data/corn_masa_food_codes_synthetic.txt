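# Synthetic stand-in for the expert-validated list of ~103 survey food codes
# for foods that could contain corn masa flour. Codes are invented (FNDDS-style)
# and pair with the synthetic survey generator; they are NOT the published list.
# columns: food_code<TAB>description
52870304	corn tortilla, variety 1
75104482	taco shell, corn, variety 1
58205775	tostada shell, variety 1
58535883	tamale, variety 1
75150572	corn tortilla chip, variety 1
58204765	enchilada, variety 1
58268876	taquito, corn tortilla, variety 1
52876028	quesadilla on corn tortilla, variety 1
58536560	masa harina dumpling, variety 1
58503334	pupusa, variety 1
58229015	sope, variety 1
58578980	gordita, corn masa, variety 1
75143133	huarache, corn masa, variety 1
58125141	atole, variety 1
75167164	corn masa pancake, variety 1
58253224	taco, soft corn tortilla, variety 1
75162782	nachos, corn chips, variety 1
58218271	chilaquiles, variety 1
75112122	tortilla soup with corn tortilla, variety 1
58170488	empanada, corn masa, variety 1
52875603	corn tortilla, variety 2
75104816	taco shell, corn, variety 2
75115091	tostada shell, variety 2
58264984	tamale, variety 2
52833746	corn tortilla chip, variety 2
58259554	enchilada, variety 2
58519418	taquito, corn tortilla, variety 2
58578961	quesadilla on corn tortilla, variety 2
75157103	masa harina dumpling, variety 2
75186464	pupusa, variety 2
58237351	sope, variety 2
58597358	gordita, corn masa, variety 2
75159217	huarache, corn masa, variety 2
75181603	atole, variety 2
58224990	corn masa pancake, variety 2
58162011	taco, soft corn tortilla, variety 2
58598550	nachos, corn chips, variety 2
58200796	chilaquiles, variety 2
75140812	tortilla soup with corn tortilla, variety 2
75161721	empanada, corn masa, variety 2
52816830	corn tortilla, variety 3
58271647	taco shell, corn, variety 3
52836630	tostada shell, variety 3
58578016	tamale, variety 3
52856506	corn tortilla chip, variety 3
52871627	enchilada, variety 3
58575154	taquito, corn tortilla, variety 3
58581313	quesadilla on corn tortilla, variety 3
52844784	masa harina dumpling, variety 3
58274990	pupusa, variety 3
58580564	sope, variety 3
58224325	gordita, corn masa, variety 3
75182653	huarache, corn masa, variety 3
58558831	atole, variety 3
75130109	corn masa pancake, variety 3
58235035	taco, soft corn tortilla, variety 3
58254535	nachos, corn chips, variety 3
58179537	chilaquiles, variety 3
75100560	tortilla soup with corn tortilla, variety 3
52854661	empanada, corn masa, variety 3
58261271	corn tortilla, variety 4
58162773	taco shell, corn, variety 4
58530697	tostada shell, variety 4
58523845	tamale, variety 4
75167090	corn tortilla chip, variety 4
52889918	enchilada, variety 4
52813391	taquito, corn tortilla, variety 4
58181290	quesadilla on corn tortilla, variety 4
75115737	masa harina dumpling, variety 4
58211899	pupusa, variety 4
58249319	sope, variety 4
58167544	gordita, corn masa, variety 4
58120105	huarache, corn masa, variety 4
58244162	atole, variety 4
58186446	corn masa pancake, variety 4
58243300	taco, soft corn tortilla, variety 4
58141761	nachos, corn chips, variety 4
52865532	chilaquiles, variety 4
58103094	tortilla soup with corn tortilla, variety 4
58579171	empanada, corn masa, variety 4
58127739	corn tortilla, variety 5
58183775	taco shell, corn, variety 5
52866980	tostada shell, variety 5
58506588	tamale, variety 5
58172814	corn tortilla chip, variety 5
58590498	enchilada, variety 5
58122617	taquito, corn tortilla, variety 5
58565440	quesadilla on corn tortilla, variety 5
58180438	masa harina dumpling, variety 5
52860270	pupusa, variety 5
58252953	sope, variety 5
58154759	gordita, corn masa, variety 5
58136401	huarache, corn masa, variety 5
75108223	atole, variety 5
58213262	corn masa pancake, variety 5
58585486	taco, soft corn tortilla, variety 5
58274905	nachos, corn chips, variety 5
75109948	chilaquiles, variety 5
58275466	tortilla soup with corn tortilla, variety 5
58549858	empanada, corn masa, variety 5
58171956	corn tortilla, variety 6
75131791	taco shell, corn, variety 6
52894926	tostada shell, variety 6
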