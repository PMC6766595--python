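group,food_no,food_desc,hcc_inf,hcc_f,low,high
fruit,1,"Apples raw fuji, with skin",3.85,3.84,3.73,3.97
fruit,2,"Apples raw gala, with skin",3.87,3.87,3.78,3.96
fruit,3,"Apples raw golden delicious",3.86,3.86,3.78,3.94
fruit,4,"Apples raw granny smith with skin",3.87,3.87,3.79,3.96
fruit,5,"Apples raw red delicious with skin",3.85,3.85,3.75,3.96
fruit,6,"Blueberries, raw",3.83,3.83,3.73,3.98
fruit,7,"Cherries, sour, red, raw",3.82,3.82,3.75,3.92
fruit,8,"Clementines raw",3.92,3.91,3.79,4.01
fruit,9,"Currants red and white raw",3.91,3.92,3.79,4.09
fruit,10,"Dates, deglet noor",3.86,3.86,3.75,3.96
fruit,11,"Dates medjool",3.78,3.78,3.73,3.84
fruit,12,"Figs dried uncooked",3.84,3.84,3.77,3.92
fruit,13,"Grapefruit raw pink and red, all areas",3.91,3.90,3.76,4.08
fruit,14,"Grapes, muscadine raw",3.89,3.89,3.82,3.95
fruit,15,"Grapes red or green, raw (European type)",3.77,3.77,3.70,3.85
fruit,16,"Jackfruit raw",3.80,3.80,3.75,3.86
fruit,17,"Kiwi fruit green raw",3.85,3.85,3.74,3.97
fruit,18,"Lemon juice, raw",3.85,3.84,3.69,3.98
fruit,19,"Lime juice, raw",3.87,3.88,3.76,4.00
fruit,20,"Melons honeydew raw",3.86,3.85,3.69,4.01
fruit,21,"Nectarines, raw",3.93,3.93,3.80,4.06
fruit,22,"Peaches yellow, raw",3.91,3.92,3.81,4.03
fruit,23,"Pears raw",3.86,3.86,3.76,3.97
fruit,24,"Pears raw bartlett",3.86,3.86,3.75,3.97
fruit,25,"Pears raw bosc",3.88,3.88,3.75,4.03
fruit,26,"Pears raw green Anjou",3.85,3.86,3.75,3.99
fruit,27,"Pears raw red Anjou",3.85,3.85,3.74,3.98
fruit,28,"Pineapple raw, all varieties",3.91,3.90,3.79,4.00
fruit,29,"Pineapple raw extra sweet variety",3.91,3.91,3.78,4.02
fruit,30,"Plums raw",3.83,3.83,3.72,3.94
fruit,31,"Rowal raw",4.00,4.00,3.94,4.06
vegetable,1,"Alfalfa seed, sprouted, raw",4.07,4.08,3.93,4.25
vegetable,2,"Brussels sprouts, raw",4.02,4.02,3.94,4.10
vegetable,3,"Cabbage, raw",3.93,3.93,3.84,4.02
vegetable,4,"Cabbage, red, raw",3.91,3.91,3.79,4.05
vegetable,5,"Carrots, baby, raw",3.97,3.97,3.83,4.13
vegetable,6,"Carrots, raw",4.01,4.02,3.90,4.19
vegetable,7,"Cucumber, with peel, raw",3.93,3.94,3.82,4.11
vegetable,8,"Lettuce, green leaf, raw",4.00,4.00,3.87,4.16
vegetable,9,"Lettuce, iceberg (includes crisphead types), raw",3.90,3.91,3.77,4.08
vegetable,10,"Mushrooms, chanterelle, raw",4.05,4.05,3.97,4.14
vegetable,11,"Mushrooms, maitake, raw",3.99,3.99,3.91,4.07
vegetable,12,"Mushrooms, portabella, raw",3.88,3.87,3.74,4.06
vegetable,13,"Okra, raw",4.05,4.06,3.95,4.16
vegetable,14,"Onions, raw",3.89,3.90,3.79,4.01
vegetable,15,"Onions, sweet, raw",3.83,3.83,3.74,3.94
vegetable,16,"Onions, yellow, sauteed",3.89,3.89,3.77,4.02
vegetable,17,"Peppers, jalapeno, raw",3.91,3.90,3.77,4.03
vegetable,18,"Peppers, sweet, green, raw",3.92,3.92,3.82,4.03
vegetable,19,"Peppers, sweet, red, raw",3.88,3.89,3.79,4.01
vegetable,20,"Radishes, raw",3.94,3.95,3.81,4.12
vegetable,21,"Rutabagas, raw",3.91,3.91,3.85,3.98
vegetable,22,"Spinach, raw",4.07,4.07,3.93,4.25
vegetable,23,"Squash, summer, zucchini, includes skin, raw",3.87,3.87,3.74,4.04
vegetable,24,"Squash, winter, butternut, raw",3.95,3.95,3.88,4.02
cereal,1,"Amaranth grain, uncooked",4.15,4.15,4.05,4.25
cereal,2,"Cornmeal, degermed, enriched, white",4.14,4.14,4.04,4.25
cereal,3,"Pasta, dry, unenriched",4.15,4.15,4.06,4.24
cereal,4,"Pasta, gluten-free, corn and rice flour, cooked",4.16,4.16,4.07,4.25
cereal,5,"Pasta, whole-wheat, cooked",4.15,4.15,4.06,4.24
cereal,6,"Potatoes, flesh, and skin, raw",4.14,4.13,3.99,4.25
cereal,7,"Potatoes, red, flesh and skin, raw",4.13,4.14,4.03,4.25
cereal,8,"Potatoes, white, flesh and skin, raw",4.13,4.13,4.04,4.23
cereal,9,"Rice, brown, long-grain, raw",4.16,4.16,4.07,4.25
cereal,10,"Rye flour, light",4.12,4.11,3.99,4.25
cereal,11,"Rye grain",4.12,4.12,4.01,4.25
cereal,12,"Sorghum flour, refined, unenriched",4.09,4.09,4.00,4.18
cereal,13,"Spelt, uncooked",4.13,4.13,4.02,4.25
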